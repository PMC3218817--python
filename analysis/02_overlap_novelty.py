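"""Compare the called interactor list against a prior FLAG-purification study.

The packaged prior fixture contains the three gene symbols the two lists
share (Cul4b, Kpna2, Top2a).  Classifying our 33 accepted interactors
against it partitions the list into 3 known and 30 novel proteins.

Writes results/novelty_report.tsv.
"""

from pathlib import Path

from insitap.consensus import accepted_interactors, call_interactors
from insitap.fixtures import load_fixture
from insitap.lists import NamedProteinList, classify_novelty, novelty_counts, venn_partition

OUT = Path(__file__).resolve().parent.parent / "results"


def main():
    table, genes, conditions = load_fixture("table2_ratios")
    calls = call_interactors(table, genes=genes, conditions=conditions)
    ours = NamedProteinList.from_iterable(
        "this_study", [c.gene for c in accepted_interactors(calls)]
    )
    prior = load_fixture("overlap_trio")

    classification = classify_novelty(ours, [prior])
    novel, known = novelty_counts(classification)
    regions = venn_partition([ours, prior])

    OUT.mkdir(exist_ok=True)
    report = OUT / "novelty_report.tsv"
    with open(report, "w") as fh:
        fh.write("gene\tstatus\tprior_studies\n")
        for gene, labels in classification.items():
            fh.write(f"{gene}\t{'known' if labels else 'novel'}\t{','.join(labels)}\n")

    print(f"our list: {len(ours)} interactors; prior list: {len(prior)} genes")
    shared = regions[("this_study", "prior_flag_study")]
    print(f"shared: {shared[0]} ({', '.join(sorted(shared[1]))})")
    print(f"novel: {novel}, known: {known}")
    print(f"wrote {report}")


if __name__ == "__main__":
    main()
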