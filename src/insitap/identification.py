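"""Dual search-engine identification consensus.

Peptide-spectrum matching platforms assign each candidate protein a
probability that the identification is correct.  Requiring a protein to
reach the probability threshold in *both* of two independent search engines
(e.g. SEQUEST and X!Tandem at 95%) is a simple and stringent way to limit
false identifications before spectral counts are compared.  Only the
protein-level filter is modelled here; peptide-level scoring happens
upstream in the search platform.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .matrix import ParseError, SpectralCountMatrix

__all__ = [
    "IdentificationRecord",
    "consensus_proteins",
    "filter_matrix",
    "read_identifications",
]


@dataclass(frozen=True)
class IdentificationRecord:
    protein_id: str
    probability: float
    engine: str

    def __post_init__(self):
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError(
                f"identification probability must be in [0,1], got {self.probability}"
            )


def _best_probabilities(records: Sequence[IdentificationRecord]) -> dict[str, float]:
    """Collapse duplicates to the best (maximum) probability per protein."""
    engines = {r.engine for r in records}
    if len(engines) > 1:
        raise ValueError(
            f"mixed engine labels within one identification list: {sorted(engines)}"
        )
    best: dict[str, float] = {}
    for r in records:
        if r.probability > best.get(r.protein_id, -1.0):
            best[r.protein_id] = r.probability
    return best


def consensus_proteins(
    records_a: Sequence[IdentificationRecord],
    records_b: Sequence[IdentificationRecord],
    threshold: float = 0.95,
) -> set[str]:
    """Proteins whose best probability reaches ``threshold`` in both engines.

    The threshold comparison is inclusive (>=).  The two lists must come from
    different engines; duplicate records per protein are collapsed to their
    maximum probability first.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    best_a = _best_probabilities(records_a)
    best_b = _best_probabilities(records_b)
    if records_a and records_b and records_a[0].engine == records_b[0].engine:
        raise ValueError("both identification lists come from the same engine")
    return {
        p
        for p, prob in best_a.items()
        if prob >= threshold and best_b.get(p, -1.0) >= threshold
    }


def filter_matrix(
    matrix: SpectralCountMatrix, accepted: Iterable[str]
) -> SpectralCountMatrix:
    """Keep only confidently identified proteins; row order is preserved."""
    return matrix.subset(accepted)


def read_identifications(path) -> list[IdentificationRecord]:
    """Read an identification TSV with columns protein_id, probability, engine."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype={"protein_id": str, "engine": str})
    except Exception as exc:  # pragma: no cover
        raise ParseError(str(exc), path=path) from exc
    required = ["protein_id", "probability", "engine"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"missing columns {missing}", path=path, line=1)
    records = []
    for i, row in df.iterrows():
        try:
            records.append(
                IdentificationRecord(row["protein_id"], float(row["probability"]), row["engine"])
            )
        except ValueError as exc:
            raise ParseError(str(exc), path=path, line=int(i) + 2, column="probability") from exc
    return records
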