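"""Packaged reference fixtures transcribed from the published study.

* ``table2_ratios`` -- the 34-row multi-tag enrichment matrix (bait row
  included); cells are tagged/control spectral-count ratios, ``Exc`` for
  detections exclusive to the tagged purification, or blank.
* ``table1_genotypes`` -- offspring genotype counts from the two
  heterozygote crosses (NTAP- and NSC-tagged alleles), with 1:2:1 expected
  weights.
* ``overlap_trio`` -- the three gene symbols shared with the largest prior
  FLAG-purification interactor list.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .enrichment import EnrichmentTable, read_ratio_table
from .lists import NamedProteinList, read_protein_list
from .mendel import GenotypeCounts

__all__ = ["FIXTURES", "load_fixture", "fixture_path"]

FIXTURES = ("table2_ratios", "table1_genotypes", "overlap_trio")

_FILES = {
    "table2_ratios": "table2_ratios.tsv",
    "table1_genotypes": "table1_genotypes.tsv",
    "overlap_trio": "overlap_trio.txt",
}


def fixture_path(name: str):
    """Filesystem path of a packaged fixture file."""
    if name not in _FILES:
        raise KeyError(f"unknown fixture {name!r}; available: {', '.join(FIXTURES)}")
    return resources.files("insitap.data") / _FILES[name]


def load_fixture(name: str):
    """Load a packaged fixture as its typed object.

    Returns, by name: ``table2_ratios`` -> ``(table, genes, conditions)``;
    ``table1_genotypes`` -> dict cross -> :class:`GenotypeCounts`;
    ``overlap_trio`` -> :class:`NamedProteinList`.
    """
    path = fixture_path(name)
    if name == "table2_ratios":
        return read_ratio_table(path)
    if name == "table1_genotypes":
        df = pd.read_csv(path, sep="\t")
        out: dict[str, GenotypeCounts] = {}
        for cross, grp in df.groupby("cross", sort=False):
            out[cross] = GenotypeCounts(
                observed=tuple(int(x) for x in grp["observed"]),
                classes=tuple(grp["genotype_class"]),
                expected_ratio=tuple(float(x) for x in grp["expected_weight"]),
            )
        return out
    return read_protein_list(path, label="prior_flag_study")
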