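"""Synthetic AP-MS generator: determinism, marginals, and caller benchmarks."""

import numpy as np
import pytest

from insitap.consensus import call_interactors
from insitap.enrichment import enrichment_table
from insitap.simulate import (
    GroundTruth,
    SimulationConfig,
    evaluate_calls,
    simulate_experiment,
)


def run_caller(config):
    matrix, truth = simulate_experiment(config)
    calls = call_interactors(enrichment_table(matrix), genes=dict(matrix.genes))
    return evaluate_calls(calls, truth)


class TestSimulateExperiment:
    def test_same_seed_gives_bit_identical_matrices(self):
        cfg = SimulationConfig(n_background=30, n_interactors=5, seed=7)
        m1, t1 = simulate_experiment(cfg)
        m2, t2 = simulate_experiment(cfg)
        assert m1 == m2
        assert t1 == t2

    def test_different_seeds_differ(self):
        m1, _ = simulate_experiment(SimulationConfig(seed=1))
        m2, _ = simulate_experiment(SimulationConfig(seed=2))
        assert m1 != m2

    def test_no_interactors_means_all_background(self):
        matrix, truth = simulate_experiment(SimulationConfig(n_interactors=0, seed=3))
        assert truth.interactor_ids == frozenset()
        assert all(p == "BAIT" or p.startswith("BG") for p in matrix.proteins)

    def test_empty_experiment_refused(self):
        with pytest.raises(ValueError, match="empty experiment"):
            SimulationConfig(n_background=0, n_interactors=0)

    def test_structure_one_tagged_and_control_pair_per_condition(self):
        cfg = SimulationConfig(n_background=5, n_interactors=2, n_fractions=5, seed=0)
        matrix, truth = simulate_experiment(cfg)
        for cond in cfg.conditions:
            for role in ("tagged", "control"):
                cols = [
                    s for s in matrix.samples if s.condition == cond and s.role == role
                ]
                assert sorted(s.fraction for s in cols) == [1, 2, 3, 4, 5]
        # bait excluded from the interactor label set
        assert "BAIT" not in truth.interactor_ids

    def test_background_control_mean_matches_bg_mean(self):
        # marginal check over >= 200 pooled control samples
        cfg = SimulationConfig(n_background=60, n_interactors=0, bg_mean=4.0, seed=5)
        totals = []
        for seed in range(4):
            matrix, _ = simulate_experiment(
                SimulationConfig(n_background=60, n_interactors=0, bg_mean=4.0, seed=seed)
            )
            pooled = matrix.pooled()
            for cond in cfg.conditions:
                totals.extend(pooled.total(cond, "control").to_numpy())
        totals = np.asarray(totals, dtype=float)
        assert totals.size >= 200
        se = np.sqrt(cfg.bg_mean / totals.size)  # Poisson standard error
        assert abs(totals.mean() - cfg.bg_mean) < 3 * se

    def test_dispersion_inflates_variance(self):
        base = SimulationConfig(n_background=200, n_interactors=0, seed=9)
        over = SimulationConfig(n_background=200, n_interactors=0, seed=9, dispersion=0.5)
        v_pois = simulate_experiment(base)[0].counts.to_numpy().var()
        v_nb = simulate_experiment(over)[0].counts.to_numpy().var()
        assert v_nb > v_pois

    def test_recall_non_decreasing_in_enrich_factor(self):
        # paired-seed mean recall may only increase as captured interactors
        # are enriched more strongly (tolerance for Monte-Carlo noise)
        seeds = range(20)
        means = []
        for enrich in (1.5, 3.0, 6.0, 12.0):
            recalls = [
                run_caller(
                    SimulationConfig(
                        n_background=40,
                        n_interactors=10,
                        capture_prob=0.9,
                        enrich_factor=enrich,
                        bg_mean=4.0,
                        leak_mean=2.0,
                        seed=s,
                    )
                ).recall
                for s in seeds
            ]
            means.append(float(np.mean(recalls)))
        for lo, hi in zip(means, means[1:]):
            assert hi >= lo - 0.02

    def test_default_conditions_recall(self):
        # strong-capture regime: the default caller recovers most interactors
        recalls = [
            run_caller(
                SimulationConfig(
                    n_background=100,
                    n_interactors=20,
                    capture_prob=0.9,
                    enrich_factor=20,
                    bg_mean=4,
                    leak_mean=0.1,
                    seed=s,
                )
            ).recall
            for s in range(30)
        ]
        assert float(np.mean(recalls)) >= 0.8


class TestEvaluateCalls:
    def _calls(self, accepted, universe):
        from insitap.consensus import InteractorCall

        return [
            InteractorCall(p, p, {}, 0, accepted=p in accepted, is_bait=False)
            for p in universe
        ]

    def test_perfect_calls(self):
        truth = GroundTruth(frozenset({"A", "B"}), {"A": {}, "B": {}})
        s = evaluate_calls(self._calls({"A", "B"}, ["A", "B", "C"]), truth)
        assert s.precision == 1.0 and s.recall == 1.0 and s.false_positives == 0

    def test_empty_accepted_is_degenerate(self):
        truth = GroundTruth(frozenset({"A"}), {"A": {}})
        s = evaluate_calls(self._calls(set(), ["A", "B", "C", "D", "E"]), truth)
        assert s.recall == 0.0 and s.precision == 1.0 and s.degenerate

    def test_partial_overlap_counts(self):
        truth = GroundTruth(frozenset({"B", "C", "D"}), {k: {} for k in "BCD"})
        s = evaluate_calls(self._calls({"A", "B", "C"}, list("ABCDE")), truth)
        assert s.precision == pytest.approx(2 / 3)
        assert s.recall == pytest.approx(2 / 3)
        assert s.false_positives == 1

    def test_unknown_truth_proteins_rejected(self):
        truth = GroundTruth(frozenset({"Z"}), {"Z": {}})
        with pytest.raises(ValueError, match="absent"):
            evaluate_calls(self._calls(set(), ["A"]), truth)
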