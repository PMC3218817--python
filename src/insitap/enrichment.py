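"""Per-condition enrichment of tagged purifications over matched controls.

The evidence a purification condition provides for a candidate interactor is
tri-state, mirroring how multi-tag AP-MS ratio tables are printed:

* ``EXCLUSIVE`` -- detected in the tagged-line purification, zero spectra in
  the matched wild-type control (printed ``Exc``).
* ``RATIO`` -- detected in both; the value is tagged/control spectral counts.
* ``NOT_DETECTED`` -- zero spectra in the tagged purification (blank cell).

Zero-control detections are kept as a distinct class rather than mapped to an
infinite or pseudocounted ratio, so published ratio tables round-trip
exactly.  A condition qualifies as supporting evidence when the detection is
exclusive or the ratio reaches the fold threshold (3-fold by default,
inclusive).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Mapping

from .matrix import CONTROL, TAGGED, ParseError, SpectralCountMatrix, pool_fractions

__all__ = [
    "EnrichmentState",
    "EnrichmentValue",
    "QualificationRule",
    "compute_enrichment",
    "qualifies",
    "enrichment_table",
    "read_ratio_table",
    "write_ratio_table",
    "round_half_up",
    "pool_fractions",
]


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero (half-up), as ratio tables print."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


class EnrichmentState(enum.Enum):
    RATIO = "ratio"
    EXCLUSIVE = "exclusive"
    NOT_DETECTED = "not_detected"


@dataclass(frozen=True)
class EnrichmentValue:
    """Tri-state enrichment for one (protein, condition)."""

    state: EnrichmentState
    value: float | None = None

    def __post_init__(self):
        if self.state is EnrichmentState.RATIO:
            if self.value is None or self.value < 0:
                raise ValueError("RATIO requires a non-negative value")
        elif self.value is not None:
            raise ValueError(f"{self.state.name} carries no numeric value")

    @classmethod
    def ratio(cls, value: float) -> "EnrichmentValue":
        return cls(EnrichmentState.RATIO, float(value))

    @classmethod
    def exclusive(cls) -> "EnrichmentValue":
        return cls(EnrichmentState.EXCLUSIVE)

    @classmethod
    def not_detected(cls) -> "EnrichmentValue":
        return cls(EnrichmentState.NOT_DETECTED)

    def format_cell(self) -> str:
        """Table cell: one-decimal half-up ratio, ``Exc``, or blank."""
        if self.state is EnrichmentState.EXCLUSIVE:
            return "Exc"
        if self.state is EnrichmentState.NOT_DETECTED:
            return ""
        return f"{round_half_up(self.value, 1):.1f}"

    @classmethod
    def parse_cell(cls, cell: str) -> "EnrichmentValue":
        cell = cell.strip()
        if cell == "" or cell.lower() in {"nd", "na"}:
            return cls.not_detected()
        if cell.lower() == "exc":
            return cls.exclusive()
        try:
            value = float(cell)
        except ValueError:
            raise ValueError(f"bad enrichment cell {cell!r}") from None
        if value < 0:
            raise ValueError(f"negative enrichment ratio {cell!r}")
        return cls.ratio(value)


NOT_DETECTED = EnrichmentValue.not_detected()


def compute_enrichment(tagged_total: int, control_total: int) -> EnrichmentValue:
    """Classify one (tagged, control) pair of pooled spectral-count totals.

    The ratio is kept at full precision; one-decimal rounding is applied only
    when formatting output cells.
    """
    if tagged_total < 0 or control_total < 0:
        raise ValueError("spectral-count totals must be >= 0")
    if tagged_total == 0:
        return EnrichmentValue.not_detected()
    if control_total == 0:
        return EnrichmentValue.exclusive()
    return EnrichmentValue.ratio(tagged_total / control_total)


@dataclass(frozen=True)
class QualificationRule:
    """Per-condition acceptance rule: exclusive, or >= fold_threshold."""

    fold_threshold: float = 3.0
    inclusive: bool = True

    def __post_init__(self):
        if not self.fold_threshold > 0:
            raise ValueError("fold_threshold must be > 0")


DEFAULT_RULE = QualificationRule()


def qualifies(e: EnrichmentValue, rule: QualificationRule = DEFAULT_RULE) -> bool:
    """Does this condition's evidence support the protein as an interactor?"""
    if e.state is EnrichmentState.EXCLUSIVE:
        return True
    if e.state is EnrichmentState.NOT_DETECTED:
        return False
    if rule.inclusive:
        return e.value >= rule.fold_threshold
    return e.value > rule.fold_threshold


EnrichmentTable = dict[str, dict[str, EnrichmentValue]]


def enrichment_table(
    matrix: SpectralCountMatrix, *, normalize: bool = False
) -> EnrichmentTable:
    """Per-condition enrichment for every protein in a count matrix.

    Fractions are pooled first, then each condition's tagged total is
    compared with its matched control total.  ``normalize=True`` rescales
    each ratio by the control/tagged sample depths (total spectra) before
    comparison; raw ratios (the default) match how published spectral-count
    ratio tables are computed.
    """
    pooled = pool_fractions(matrix)
    conditions = pooled.conditions
    tagged = {c: pooled.total(c, TAGGED).to_numpy() for c in conditions}
    control = {c: pooled.total(c, CONTROL).to_numpy() for c in conditions}
    factors = {}
    for cond in conditions:
        if normalize:
            t_depth, c_depth = int(tagged[cond].sum()), int(control[cond].sum())
            factors[cond] = (c_depth / t_depth) if t_depth and c_depth else 1.0
        else:
            factors[cond] = 1.0
    table: EnrichmentTable = {}
    for i, protein in enumerate(pooled.proteins):
        row: dict[str, EnrichmentValue] = {}
        for cond in conditions:
            e = compute_enrichment(int(tagged[cond][i]), int(control[cond][i]))
            if e.state is EnrichmentState.RATIO and factors[cond] != 1.0:
                e = EnrichmentValue.ratio(e.value * factors[cond])
            row[cond] = e
        table[protein] = row
    return table


# ---------------------------------------------------------------------------
# Ratio-table TSV dialect: protein_id, gene, one column per condition;
# cells are a decimal ratio, "Exc", or blank.
# ---------------------------------------------------------------------------

_REPORT_COLUMNS = {"qualifying_conditions", "accepted", "is_bait"}


def read_ratio_table(path) -> tuple[EnrichmentTable, dict[str, str], list[str]]:
    """Parse a ratio-table TSV.

    Returns ``(table, genes, conditions)`` where ``table`` maps protein id ->
    condition -> :class:`EnrichmentValue` in file order.  Trailing call-report
    columns (``qualifying_conditions``, ``accepted``, ``is_bait``) are
    ignored, so call reports parse with the same reader.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise ParseError("empty ratio table", path=path)
    header = lines[0].split("\t")
    if header[:2] != ["protein_id", "gene"]:
        raise ParseError(
            "ratio table must start with columns protein_id, gene", path=path, line=1
        )
    conditions = [c for c in header[2:] if c not in _REPORT_COLUMNS]
    table: EnrichmentTable = {}
    genes: dict[str, str] = {}
    for lineno, raw in enumerate(lines[1:], start=2):
        if not raw.strip():
            continue
        cells = raw.split("\t")
        cells += [""] * (len(header) - len(cells))
        if len(cells) > len(header):
            raise ParseError("more cells than header columns", path=path, line=lineno)
        protein_id, gene = cells[0], cells[1]
        if protein_id in table:
            raise ParseError(
                f"duplicate protein_id {protein_id!r}", path=path, line=lineno
            )
        row: dict[str, EnrichmentValue] = {}
        for cond, cell in zip(conditions, cells[2 : 2 + len(conditions)]):
            try:
                row[cond] = EnrichmentValue.parse_cell(cell)
            except ValueError as exc:
                raise ParseError(str(exc), path=path, line=lineno, column=cond) from exc
        table[protein_id] = row
        genes[protein_id] = gene
    return table, genes, conditions


def write_ratio_table(
    table: EnrichmentTable,
    genes: Mapping[str, str],
    path,
    conditions: list[str] | None = None,
) -> None:
    """Write the ratio-table TSV dialect (no call-report columns)."""
    if conditions is None:
        conditions = _union_conditions(table)
    with open(path, "w") as fh:
        fh.write("\t".join(["protein_id", "gene", *conditions]) + "\n")
        for protein_id, row in table.items():
            cells = [row.get(c, NOT_DETECTED).format_cell() for c in conditions]
            fh.write("\t".join([protein_id, genes.get(protein_id, ""), *cells]) + "\n")


def _union_conditions(table: EnrichmentTable) -> list[str]:
    seen: dict[str, None] = {}
    for row in table.values():
        for cond in row:
            seen.setdefault(cond, None)
    return list(seen)
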