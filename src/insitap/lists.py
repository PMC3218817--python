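"""Cross-study interactor-list algebra: Venn partitions and novelty.

Interactor lists from different studies are compared as sets of
case-normalized gene symbols.  Matching is exact after normalization; no
alias or orthology resolution is attempted (same-species studies reported
by symbol are the intended use).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "NamedProteinList",
    "normalize_symbol",
    "venn_partition",
    "classify_novelty",
    "novelty_counts",
    "read_protein_list",
]


def normalize_symbol(symbol: str) -> str:
    """Canonical case for a gene symbol (mouse convention: Xxxx1)."""
    s = symbol.strip()
    return s[:1].upper() + s[1:].lower() if s else s


@dataclass(frozen=True)
class NamedProteinList:
    """A study's interactor list as a set of normalized gene symbols."""

    label: str
    members: frozenset[str]

    @classmethod
    def from_iterable(cls, label: str, symbols: Iterable[str]) -> "NamedProteinList":
        return cls(label, frozenset(normalize_symbol(s) for s in symbols if s.strip()))

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, symbol: str) -> bool:
        return normalize_symbol(symbol) in self.members


Region = tuple[str, ...]


def venn_partition(
    lists: Sequence[NamedProteinList],
) -> dict[Region, tuple[int, frozenset[str]]]:
    """Disjoint Venn regions of two or three protein lists.

    Returns a map from region key -- the tuple of labels whose lists contain
    the region, in input order -- to ``(size, members)``.  All 2**n - 1
    regions are reported, including empty ones; their union recovers each
    input list exactly.
    """
    if len(lists) not in (2, 3):
        raise ValueError(f"venn_partition takes 2 or 3 lists, got {len(lists)}")
    labels = [pl.label for pl in lists]
    if len(set(labels)) != len(labels):
        raise ValueError("list labels must be distinct")
    for pl in lists:
        if not pl.members:
            raise ValueError(f"list {pl.label!r} is empty")
    universe = frozenset().union(*(pl.members for pl in lists))
    by_label = {pl.label: pl.members for pl in lists}
    regions: dict[Region, tuple[int, frozenset[str]]] = {}
    for r in range(1, len(labels) + 1):
        for inside in combinations(labels, r):
            members = universe
            for lab in inside:
                members = members & by_label[lab]
            for lab in labels:
                if lab not in inside:
                    members = members - by_label[lab]
            regions[tuple(inside)] = (len(members), frozenset(members))
    return regions


def classify_novelty(
    ours: NamedProteinList, priors: Sequence[NamedProteinList]
) -> dict[str, tuple[str, ...]]:
    """For each of our genes, the labels of prior studies that reported it.

    An empty tuple marks a novel gene (absent from every prior list); the
    classification covers every member of ``ours`` exactly once.
    """
    return {
        gene: tuple(p.label for p in priors if gene in p.members)
        for gene in sorted(ours.members)
    }


def novelty_counts(classification: dict[str, tuple[str, ...]]) -> tuple[int, int]:
    """(novel, known) counts from a :func:`classify_novelty` map."""
    novel = sum(1 for labels in classification.values() if not labels)
    return novel, len(classification) - novel


def read_protein_list(path, label: str | None = None) -> NamedProteinList:
    """Read a plain-text gene list: one symbol per line, ``#`` comments."""
    path = Path(path)
    symbols = []
    for raw in path.read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if line:
            symbols.append(line)
    return NamedProteinList.from_iterable(label or path.stem, symbols)
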