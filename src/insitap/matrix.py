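"""Spectral-count matrices for multi-tag AP-MS experiments.

A purification experiment is a proteins x samples table of non-negative
integer spectral counts.  Each sample belongs to a tag condition (e.g. CBP,
FLAG, HIS, S), plays one of two roles -- a ``tagged``-line purification or
the matched wild-type ``control`` purification -- and may be one of several
gel-lane fractions that together make up the purification lane.

Sample columns are named ``<condition>:<role>[:<fraction>]`` in the on-disk
TSV dialect, e.g. ``FLAG:tagged:1`` or ``FLAG:control:1``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

TAGGED = "tagged"
CONTROL = "control"
_ROLES = (TAGGED, CONTROL)


class ParseError(ValueError):
    """Malformed input file; carries file, line and column context."""

    def __init__(self, message: str, *, path=None, line=None, column=None):
        ctx = []
        if path is not None:
            ctx.append(f"file {path}")
        if line is not None:
            ctx.append(f"line {line}")
        if column is not None:
            ctx.append(f"column {column!r}")
        super().__init__(f"{message} ({', '.join(ctx)})" if ctx else message)
        self.path, self.line, self.column = path, line, column


@dataclass(frozen=True)
class Sample:
    """Descriptor of one sample column."""

    condition: str
    role: str
    fraction: int | None = None

    def __post_init__(self):
        if self.role not in _ROLES:
            raise ValueError(f"sample role must be one of {_ROLES}, got {self.role!r}")
        if self.fraction is not None and self.fraction < 1:
            raise ValueError("fraction index is 1-based")

    @property
    def name(self) -> str:
        if self.fraction is None:
            return f"{self.condition}:{self.role}"
        return f"{self.condition}:{self.role}:{self.fraction}"

    @classmethod
    def parse(cls, name: str) -> "Sample":
        parts = name.split(":")
        if len(parts) == 2:
            return cls(parts[0], parts[1])
        if len(parts) == 3:
            try:
                frac = int(parts[2])
            except ValueError:
                raise ValueError(f"bad fraction index in sample name {name!r}") from None
            return cls(parts[0], parts[1], frac)
        raise ValueError(
            f"sample name {name!r} is not of the form condition:role[:fraction]"
        )


class SpectralCountMatrix:
    """Non-negative integer spectral counts, proteins x samples.

    Parameters
    ----------
    counts
        DataFrame indexed by protein identifier; columns are sample names in
        the ``condition:role[:fraction]`` dialect.
    genes
        Optional gene symbols aligned with the protein index.  Missing
        symbols default to the empty string.
    """

    def __init__(self, counts: pd.DataFrame, genes: pd.Series | None = None):
        counts = counts.copy()
        arr = counts.to_numpy()
        if arr.size and (not np.issubdtype(arr.dtype, np.integer)):
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("spectral counts must be integers")
            counts = counts.round().astype(np.int64)
        if counts.size and (counts.to_numpy() < 0).any():
            raise ValueError("spectral counts must be >= 0")
        if counts.index.has_duplicates:
            raise ValueError("duplicate protein identifiers")
        if counts.columns.has_duplicates:
            raise ValueError("duplicate sample names")
        self.counts = counts.astype(np.int64)
        if genes is None:
            genes = pd.Series("", index=counts.index, dtype=object)
        self.genes = genes.reindex(counts.index).fillna("").astype(str)
        self._samples = [Sample.parse(c) for c in counts.columns]
        self._check_matched_controls()

    def _check_matched_controls(self):
        tagged = {s.condition for s in self._samples if s.role == TAGGED}
        control = {s.condition for s in self._samples if s.role == CONTROL}
        missing = tagged - control
        if missing:
            raise ValueError(
                "tagged samples without a matched control purification: "
                + ", ".join(sorted(missing))
            )

    # -- introspection ----------------------------------------------------
    @property
    def proteins(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[Sample]:
        return list(self._samples)

    @property
    def conditions(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self._samples:
            seen.setdefault(s.condition, None)
        return list(seen)

    @property
    def n_proteins(self) -> int:
        return len(self.counts.index)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, SpectralCountMatrix)
            and self.counts.equals(other.counts)
            and self.genes.equals(other.genes)
        )

    # -- transformations --------------------------------------------------
    def subset(self, accepted: Iterable[str]) -> "SpectralCountMatrix":
        """Row-subset to ``accepted`` proteins, preserving input order."""
        accepted = set(accepted)
        keep = [p for p in self.counts.index if p in accepted]
        return SpectralCountMatrix(self.counts.loc[keep], self.genes.loc[keep])

    def pooled(self) -> "SpectralCountMatrix":
        """Sum fraction columns of each (condition, role) sample into one."""
        groups: dict[str, list[str]] = {}
        for s in self._samples:
            key = Sample(s.condition, s.role).name
            groups.setdefault(key, []).append(s.name)
        pooled = pd.DataFrame(
            {key: self.counts[cols].sum(axis=1) for key, cols in groups.items()},
            index=self.counts.index,
        )
        return SpectralCountMatrix(pooled, self.genes)

    def total(self, condition: str, role: str) -> pd.Series:
        """Per-protein pooled total for one (condition, role) sample."""
        cols = [s.name for s in self._samples if s.condition == condition and s.role == role]
        return self.counts[cols].sum(axis=1)

    # -- I/O ---------------------------------------------------------------
    def to_tsv(self, path) -> None:
        out = self.counts.copy()
        out.insert(0, "gene", self.genes)
        out.to_csv(path, sep="\t", index_label="protein_id")

    @classmethod
    def from_tsv(cls, path) -> "SpectralCountMatrix":
        path = Path(path)
        try:
            df = pd.read_csv(path, sep="\t", dtype={"protein_id": str, "gene": str})
        except Exception as exc:  # pragma: no cover - pandas message passthrough
            raise ParseError(str(exc), path=path) from exc
        if df.columns[0] != "protein_id" or (len(df.columns) > 1 and df.columns[1] != "gene"):
            raise ParseError(
                "count TSV must start with columns protein_id, gene", path=path, line=1
            )
        sample_cols = list(df.columns[2:])
        for col in sample_cols:
            try:
                Sample.parse(col)
            except ValueError as exc:
                raise ParseError(str(exc), path=path, line=1, column=col) from exc
        counts = df.set_index("protein_id")[sample_cols]
        for col in sample_cols:
            bad = pd.to_numeric(counts[col], errors="coerce")
            if bad.isna().any():
                row = int(np.flatnonzero(bad.isna().to_numpy())[0])
                raise ParseError(
                    f"non-numeric spectral count {counts[col].iloc[row]!r}",
                    path=path,
                    line=row + 2,
                    column=col,
                )
        genes = df.set_index("protein_id")["gene"].fillna("")
        return cls(counts.astype(np.int64), genes)


def pool_fractions(matrix: SpectralCountMatrix) -> SpectralCountMatrix:
    """Pool gel-lane fraction columns into one column per (condition, role).

    Total spectral count per protein is conserved; protein order is
    unchanged.  A matrix that is already single-fraction (no fraction index
    in any sample name) is returned as an equal pooled copy.
    """
    return matrix.pooled()
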