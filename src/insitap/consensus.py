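"""In silico tandem affinity purification: k-of-n consensus interactor calls.

Instead of a physical two-resin tandem purification, independent single-tag
purifications are intersected computationally: a protein is accepted as a
bait interactor when its enrichment over the matched control qualifies in at
least ``k`` of the ``n`` tag conditions (k=2 of n=4 by default).  The bait
itself is called and flagged but never counted among the interactors.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

from .enrichment import (
    DEFAULT_RULE,
    EnrichmentTable,
    EnrichmentValue,
    QualificationRule,
    read_ratio_table,
    qualifies,
)

__all__ = [
    "CallingConfig",
    "InteractorCall",
    "call_interactors",
    "accepted_interactors",
    "write_call_report",
    "read_call_report",
]

DEFAULT_BAIT = "Pou5f1"


@dataclass(frozen=True)
class CallingConfig:
    """Parameters of the k-of-n consensus call."""

    k_min_support: int = 2
    n_conditions: int = 4
    rule: QualificationRule = DEFAULT_RULE
    bait_id: str = DEFAULT_BAIT

    def __post_init__(self):
        if not 1 <= self.k_min_support <= self.n_conditions:
            raise ValueError(
                f"need 1 <= k_min_support <= n_conditions, got "
                f"k={self.k_min_support}, n={self.n_conditions}"
            )


@dataclass
class InteractorCall:
    """Per-protein outcome of the consensus call."""

    protein_id: str
    gene: str
    enrichment: dict[str, EnrichmentValue]
    qualifying_conditions: int
    accepted: bool
    is_bait: bool


def call_interactors(
    enrichment_table: EnrichmentTable,
    config: CallingConfig = CallingConfig(),
    genes: Mapping[str, str] | None = None,
    conditions: list[str] | None = None,
) -> list[InteractorCall]:
    """Apply the k-of-n qualification consensus to an enrichment table.

    ``enrichment_table`` maps protein id -> condition -> enrichment value;
    conditions missing from a protein's row count as not detected and
    contribute no support.  One call is produced per input protein, in input
    order.  The bait (matched by protein id or gene symbol against
    ``config.bait_id``) is flagged ``is_bait`` and never accepted.
    """
    genes = dict(genes or {})
    if conditions is None:
        seen: dict[str, None] = {}
        for row in enrichment_table.values():
            for cond in row:
                seen.setdefault(cond, None)
        conditions = list(seen)
    if conditions and config.k_min_support > len(conditions):
        raise ValueError(
            f"k_min_support={config.k_min_support} exceeds the "
            f"{len(conditions)} available conditions"
        )
    calls = []
    for protein_id, row in enrichment_table.items():
        gene = genes.get(protein_id, "")
        enrichment = {
            cond: row.get(cond, EnrichmentValue.not_detected()) for cond in conditions
        }
        support = sum(qualifies(e, config.rule) for e in enrichment.values())
        is_bait = config.bait_id in (protein_id, gene)
        calls.append(
            InteractorCall(
                protein_id=protein_id,
                gene=gene,
                enrichment=enrichment,
                qualifying_conditions=support,
                accepted=(not is_bait) and support >= config.k_min_support,
                is_bait=is_bait,
            )
        )
    return calls


def accepted_interactors(calls: list[InteractorCall]) -> list[InteractorCall]:
    """The accepted, non-bait calls (the interactor list)."""
    return [c for c in calls if c.accepted and not c.is_bait]


def write_call_report(
    calls: list[InteractorCall], destination, conditions: list[str] | None = None
) -> None:
    """Write calls as ratio-table TSV plus qualification columns.

    Ratio cells are formatted one-decimal half-up; the extra columns are
    ``qualifying_conditions``, ``accepted`` and ``is_bait``.
    """
    if conditions is None:
        seen: dict[str, None] = {}
        for c in calls:
            for cond in c.enrichment:
                seen.setdefault(cond, None)
        conditions = list(seen)
    path = Path(destination)
    with open(path, "w") as fh:
        header = ["protein_id", "gene", *conditions, "qualifying_conditions", "accepted", "is_bait"]
        fh.write("\t".join(header) + "\n")
        for c in calls:
            cells = [
                c.enrichment.get(cond, EnrichmentValue.not_detected()).format_cell()
                for cond in conditions
            ]
            fh.write(
                "\t".join(
                    [
                        c.protein_id,
                        c.gene,
                        *cells,
                        str(c.qualifying_conditions),
                        str(c.accepted),
                        str(c.is_bait),
                    ]
                )
                + "\n"
            )


def read_call_report(path) -> tuple[EnrichmentTable, dict[str, str], list[str]]:
    """Parse the enrichment part of a call report (states and ratio values)."""
    return read_ratio_table(path)
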