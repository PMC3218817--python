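import random

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=50, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

from insitap.enrichment import EnrichmentValue
from insitap.fixtures import load_fixture


@pytest.fixture(scope="session")
def table2():
    """(table, genes, conditions) of the packaged published ratio matrix."""
    return load_fixture("table2_ratios")


@pytest.fixture(scope="session")
def table1():
    """Genotype counts of the two heterozygote crosses."""
    return load_fixture("table1_genotypes")


def random_enrichment_table(rng: random.Random, n_proteins=8, conditions=("CBP", "FLAG", "HIS", "S")):
    """Small random tri-state enrichment table for oracle comparisons."""
    table = {}
    for i in range(n_proteins):
        row = {}
        for cond in conditions:
            u = rng.random()
            if u < 0.3:
                row[cond] = EnrichmentValue.not_detected()
            elif u < 0.55:
                row[cond] = EnrichmentValue.exclusive()
            else:
                row[cond] = EnrichmentValue.ratio(round(rng.uniform(0, 8), 1))
        table[f"P{i:02d}"] = row
    return table
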