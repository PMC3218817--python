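"""Mendelian genotype-ratio statistics for heterozygote-cross offspring.

A het x het cross of a single locus segregates 1:2:1
(wild-type : heterozygous : homozygous).  Departures -- e.g. loss of the
homozygous class when the modified allele is not tolerated -- are assessed
with the Pearson chi-square goodness-of-fit test on genotyped offspring
counts: X^2 = sum (obs - exp)^2 / exp on k - 1 degrees of freedom, with the
upper-tail p-value given by the regularized upper incomplete gamma function
Q(df/2, X^2/2).
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.special import gammaincc

from .enrichment import round_half_up

__all__ = ["GenotypeCounts", "GofResult", "class_percentages", "class_fractions", "pearson_gof"]

DEFAULT_CLASSES = ("wild_type", "heterozygous", "homozygous")
DEFAULT_RATIO = (1.0, 2.0, 1.0)


@dataclass(frozen=True)
class GenotypeCounts:
    """Observed offspring counts per genotype class, with expected weights."""

    observed: tuple[int, ...]
    classes: tuple[str, ...] = DEFAULT_CLASSES
    expected_ratio: tuple[float, ...] = DEFAULT_RATIO

    def __post_init__(self):
        if len(self.observed) != len(self.classes) or len(self.expected_ratio) != len(
            self.classes
        ):
            raise ValueError("observed, classes and expected_ratio lengths differ")
        if any(o < 0 for o in self.observed):
            raise ValueError("observed counts must be >= 0")
        if self.total <= 0:
            raise ValueError("total observed count must be > 0")
        if any(w <= 0 for w in self.expected_ratio):
            raise ValueError("expected_ratio weights must be > 0")

    @property
    def total(self) -> int:
        return int(sum(self.observed))

    @property
    def expected(self) -> tuple[float, ...]:
        wsum = sum(self.expected_ratio)
        return tuple(self.total * w / wsum for w in self.expected_ratio)


def class_fractions(counts: GenotypeCounts) -> tuple[float, ...]:
    """Unrounded per-class fractions of the genotyped total."""
    return tuple(o / counts.total for o in counts.observed)


def class_percentages(counts: GenotypeCounts) -> tuple[float, ...]:
    """Per-class percentages, rounded half-up to one decimal for display."""
    return tuple(round_half_up(100.0 * f, 1) for f in class_fractions(counts))


@dataclass(frozen=True)
class GofResult:
    statistic: float
    df: int
    pvalue: float


def pearson_gof(counts: GenotypeCounts) -> GofResult:
    """Pearson chi-square goodness of fit against the expected ratio.

    No continuity correction is applied.  The statistic is invariant under
    uniform rescaling of the expected-ratio weights.
    """
    expected = counts.expected
    if any(e <= 0 for e in expected):
        raise ValueError("expected counts must all be > 0")
    statistic = sum((o - e) ** 2 / e for o, e in zip(counts.observed, expected))
    df = len(counts.classes) - 1
    pvalue = float(gammaincc(df / 2.0, statistic / 2.0))
    return GofResult(statistic=float(statistic), df=df, pvalue=pvalue)
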