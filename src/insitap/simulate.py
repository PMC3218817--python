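"""Synthetic multi-tag AP-MS experiments with known ground truth.

The generator emulates a low-input nuclear-extract purification series: one
tagged and one matched wild-type control purification per tag condition,
each gel lane cut into fractions that are digested and measured separately.
Spectral counts are small integers; the bait lands around a dozen spectra
per tagged lane.

Generative model (per pooled sample; fractions split the mean evenly and
are drawn independently, so pooled totals keep the stated means):

* background contaminant: mean ``bg_mean`` in *both* tagged and control
  samples of every condition -- resin/buffer background binds regardless of
  the bait;
* true interactor: each condition can capture it with probability
  ``capture_prob`` (its purification chemistry may or may not preserve the
  interaction; drawn once per experiment and reported in the ground truth).
  Captured: mean ``bg_mean * enrich_factor`` in the tagged sample.  In
  controls, and in tagged samples of non-capturing conditions, only a small
  leak mean ``leak_mean`` (frequent zeros);
* bait: mean ``bait_mean`` in every tagged sample, ``leak_mean`` in controls.

Counts are Poisson by default; an optional negative-binomial dispersion adds
over-dispersion for robustness experiments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .consensus import InteractorCall
from .matrix import SpectralCountMatrix

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "PerformanceSummary",
    "simulate_experiment",
    "evaluate_calls",
    "write_ground_truth",
    "read_ground_truth",
]

DEFAULT_CONDITIONS = ("CBP", "FLAG", "HIS", "S")
BAIT_ID = "BAIT"


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters for one synthetic experiment.

    Means are per pooled sample (summed over fractions), in spectra.
    ``capture_prob`` may be a single probability applied to every condition
    or a mapping from condition label to probability.
    """

    n_background: int = 100
    n_interactors: int = 20
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS
    capture_prob: float | Mapping[str, float] = 0.5
    bg_mean: float = 4.0
    enrich_factor: float = 10.0
    leak_mean: float = 0.2
    bait_mean: float = 11.0
    n_fractions: int = 5
    seed: int = 0
    dispersion: float | None = None  # NB size parameter; None = Poisson

    def __post_init__(self):
        if self.n_background < 0 or self.n_interactors < 0:
            raise ValueError("protein counts must be >= 0")
        if self.n_background <= 0 and self.n_interactors <= 0:
            raise ValueError("empty experiment: no background and no interactors")
        if not self.conditions:
            raise ValueError("need at least one condition")
        if len(set(self.conditions)) != len(self.conditions):
            raise ValueError("duplicate condition labels")
        for cond in self.conditions:
            p = self.capture_probability(cond)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"capture_prob for {cond} must be in [0,1], got {p}")
        for name in ("bg_mean", "enrich_factor", "leak_mean", "bait_mean"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_fractions < 1:
            raise ValueError("n_fractions must be >= 1")
        if self.dispersion is not None and self.dispersion <= 0:
            raise ValueError("dispersion must be > 0 when given")

    def capture_probability(self, condition: str) -> float:
        if isinstance(self.capture_prob, Mapping):
            return float(self.capture_prob[condition])
        return float(self.capture_prob)


@dataclass(frozen=True)
class GroundTruth:
    """True interactor labels and the per-condition capture pattern."""

    interactor_ids: frozenset[str]
    capture_map: dict[str, dict[str, bool]]  # interactor -> condition -> capturable
    bait_id: str = BAIT_ID

    def can_capture(self, interactor: str, condition: str) -> bool:
        return self.capture_map[interactor][condition]


def _draw_counts(rng: np.random.Generator, means, dispersion: float | None):
    """Integer counts with the given means: Poisson, or NB if over-dispersed."""
    means = np.asarray(means, dtype=float)
    if dispersion is None:
        return rng.poisson(means).astype(np.int64)
    # NB parametrised by mean and size r: p = r / (r + mean); mean 0 -> p 1 -> 0
    r = dispersion
    return rng.negative_binomial(r, r / (r + means)).astype(np.int64)


def simulate_experiment(config: SimulationConfig) -> tuple[SpectralCountMatrix, GroundTruth]:
    """Generate one experiment; same config and seed give identical output."""
    rng = np.random.default_rng(config.seed)
    interactors = [f"INT{i + 1:03d}" for i in range(config.n_interactors)]
    background = [f"BG{i + 1:04d}" for i in range(config.n_background)]
    proteins = [BAIT_ID, *interactors, *background]

    capture = {
        i: {
            cond: bool(rng.random() < config.capture_probability(cond))
            for cond in config.conditions
        }
        for i in interactors
    }

    # per-protein mean in the pooled tagged / control sample of each condition
    columns: dict[str, np.ndarray] = {}
    n = len(proteins)
    for cond in config.conditions:
        tagged_mean = np.empty(n)
        control_mean = np.empty(n)
        tagged_mean[0] = config.bait_mean
        control_mean[0] = config.leak_mean
        for j, prot in enumerate(interactors, start=1):
            captured = capture[prot][cond]
            tagged_mean[j] = (
                config.bg_mean * config.enrich_factor if captured else config.leak_mean
            )
            control_mean[j] = config.leak_mean
        tagged_mean[1 + len(interactors):] = config.bg_mean
        control_mean[1 + len(interactors):] = config.bg_mean
        for role, sample_mean in (("tagged", tagged_mean), ("control", control_mean)):
            per_fraction = sample_mean / config.n_fractions
            for frac in range(1, config.n_fractions + 1):
                name = (
                    f"{cond}:{role}:{frac}"
                    if config.n_fractions > 1
                    else f"{cond}:{role}"
                )
                columns[name] = _draw_counts(rng, per_fraction, config.dispersion)

    frame = pd.DataFrame(columns, index=pd.Index(proteins, name="protein_id"))
    matrix = SpectralCountMatrix(frame, genes=pd.Series(proteins, index=proteins))
    truth = GroundTruth(interactor_ids=frozenset(interactors), capture_map=capture)
    return matrix, truth


@dataclass(frozen=True)
class PerformanceSummary:
    """Precision/recall of a call set against ground truth."""

    precision: float
    recall: float
    false_positives: int
    n_accepted: int
    n_true: int
    degenerate: bool  # no protein accepted; precision 1.0 by convention


def evaluate_calls(calls: Sequence[InteractorCall], truth: GroundTruth) -> PerformanceSummary:
    """Score accepted calls against the simulated ground truth."""
    universe = {c.protein_id for c in calls}
    unknown = truth.interactor_ids - universe
    if unknown:
        raise ValueError(
            f"ground truth references proteins absent from the calls: {sorted(unknown)[:5]}"
        )
    accepted = {c.protein_id for c in calls if c.accepted and not c.is_bait}
    true = truth.interactor_ids
    tp = len(accepted & true)
    fp = len(accepted - true)
    degenerate = len(accepted) == 0
    precision = 1.0 if degenerate else tp / len(accepted)
    recall = tp / len(true) if true else 0.0
    return PerformanceSummary(
        precision=precision,
        recall=recall,
        false_positives=fp,
        n_accepted=len(accepted),
        n_true=len(true),
        degenerate=degenerate,
    )


def write_ground_truth(truth: GroundTruth, path, conditions: Sequence[str]) -> None:
    """TSV: protein_id, is_interactor, one capture-flag column per condition."""
    with open(path, "w") as fh:
        fh.write("\t".join(["protein_id", "is_interactor", *conditions]) + "\n")
        for prot in sorted(truth.interactor_ids):
            flags = ["1" if truth.can_capture(prot, c) else "0" for c in conditions]
            fh.write("\t".join([prot, "1", *flags]) + "\n")


def read_ground_truth(path) -> GroundTruth:
    df = pd.read_csv(path, sep="\t", dtype=str)
    conditions = [c for c in df.columns if c not in ("protein_id", "is_interactor")]
    capture = {
        row["protein_id"]: {c: row[c] == "1" for c in conditions}
        for _, row in df.iterrows()
        if row["is_interactor"] == "1"
    }
    return GroundTruth(interactor_ids=frozenset(capture), capture_map=capture)
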