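"""k-of-n consensus interactor calling and call reports."""

import random

import pytest

from conftest import random_enrichment_table
from insitap.consensus import (
    CallingConfig,
    accepted_interactors,
    call_interactors,
    read_call_report,
    write_call_report,
)
from insitap.enrichment import (
    EnrichmentState,
    EnrichmentValue,
    QualificationRule,
    qualifies,
)


def brute_force_accepted(table, k, fold, bait="Pou5f1", genes=None):
    """Independent oracle: enumerate each protein's qualifying conditions."""
    genes = genes or {}
    accepted = set()
    for protein, row in table.items():
        support = 0
        for e in row.values():
            if e.state is EnrichmentState.EXCLUSIVE:
                support += 1
            elif e.state is EnrichmentState.RATIO and e.value >= fold:
                support += 1
        if support >= k and bait not in (protein, genes.get(protein, "")):
            accepted.add(protein)
    return accepted


class TestCallInteractors:
    def test_single_exclusive_condition_is_rejected(self):
        table = {
            "X": {
                "CBP": EnrichmentValue.exclusive(),
                "FLAG": EnrichmentValue.not_detected(),
                "HIS": EnrichmentValue.not_detected(),
                "S": EnrichmentValue.not_detected(),
            }
        }
        (call,) = call_interactors(table)
        assert call.qualifying_conditions == 1
        assert not call.accepted

    def test_missing_conditions_count_as_no_support(self):
        table = {"X": {"CBP": EnrichmentValue.exclusive()}}
        (call,) = call_interactors(table, conditions=["CBP", "FLAG", "HIS", "S"])
        assert call.enrichment["FLAG"].state is EnrichmentState.NOT_DETECTED
        assert call.qualifying_conditions == 1

    def test_bait_is_flagged_and_never_counted(self, table2):
        table, genes, conds = table2
        calls = call_interactors(table, genes=genes, conditions=conds)
        baits = [c for c in calls if c.is_bait]
        assert [c.gene for c in baits] == ["Pou5f1"]
        assert not baits[0].accepted
        assert baits[0] not in accepted_interactors(calls)

    def test_published_table_reproduces_headline_count(self, table2):
        table, genes, conds = table2
        calls = call_interactors(table, genes=genes, conditions=conds)
        accepted = accepted_interactors(calls)
        assert len(calls) == 34
        assert len(accepted) == 33
        # the published list satisfies its own rule: every non-bait row >= 2
        assert all(c.qualifying_conditions >= 2 for c in calls if not c.is_bait)

    def test_invalid_k_rejected(self):
        with pytest.raises(ValueError):
            CallingConfig(k_min_support=5, n_conditions=4)
        with pytest.raises(ValueError):
            call_interactors(
                {"X": {"CBP": EnrichmentValue.exclusive()}},
                CallingConfig(k_min_support=2, n_conditions=4),
                conditions=["CBP"],
            )

    def test_matches_brute_force_oracle_on_random_tables(self):
        rng = random.Random(11)
        for _ in range(200):
            table = random_enrichment_table(rng)
            config = CallingConfig(
                k_min_support=rng.randint(1, 4),
                rule=QualificationRule(fold_threshold=rng.choice([2.0, 3.0, 4.0])),
            )
            calls = call_interactors(table, config)
            got = {c.protein_id for c in accepted_interactors(calls)}
            want = brute_force_accepted(
                table, config.k_min_support, config.rule.fold_threshold
            )
            assert got == want

    def test_accepted_set_shrinks_with_k(self):
        rng = random.Random(13)
        for _ in range(25):
            table = random_enrichment_table(rng, n_proteins=12)
            previous = None
            for k in (1, 2, 3, 4):
                calls = call_interactors(table, CallingConfig(k_min_support=k))
                acc = {c.protein_id for c in accepted_interactors(calls)}
                if previous is not None:
                    assert acc <= previous
                previous = acc

    def test_accepted_set_shrinks_with_fold_threshold(self):
        rng = random.Random(17)
        for _ in range(25):
            table = random_enrichment_table(rng, n_proteins=12)
            previous = None
            for fold in (1.5, 3.0, 5.0, 8.0):
                calls = call_interactors(
                    table, CallingConfig(rule=QualificationRule(fold_threshold=fold))
                )
                acc = {c.protein_id for c in accepted_interactors(calls)}
                if previous is not None:
                    assert acc <= previous
                previous = acc

    def test_qualifying_count_matches_rule_application(self):
        rng = random.Random(19)
        rule = QualificationRule()
        for _ in range(20):
            table = random_enrichment_table(rng)
            for call in call_interactors(table, CallingConfig(rule=rule)):
                assert call.qualifying_conditions == sum(
                    qualifies(e, rule) for e in call.enrichment.values()
                )


class TestCallReport:
    def test_empty_call_list_writes_header_only(self, tmp_path):
        path = tmp_path / "calls.tsv"
        write_call_report([], path, conditions=["CBP", "FLAG"])
        lines = path.read_text().splitlines()
        assert len(lines) == 1 and lines[0].startswith("protein_id\tgene\tCBP\tFLAG")

    def test_write_then_read_reproduces_states_and_values(self, tmp_path):
        rng = random.Random(23)
        table = random_enrichment_table(rng)
        calls = call_interactors(table)
        path = tmp_path / "calls.tsv"
        write_call_report(calls, path)
        again, _, conds = read_call_report(path)
        for call in calls:
            for cond in conds:
                orig, back = call.enrichment[cond], again[call.protein_id][cond]
                assert back.state is orig.state
                if orig.state is EnrichmentState.RATIO:
                    assert back.value == pytest.approx(round(orig.value, 1), abs=0.051)
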