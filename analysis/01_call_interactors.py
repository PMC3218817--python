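"""Call bait interactors from the packaged multi-tag enrichment matrix.

Applies the default in silico TAP rule -- a condition supports a protein if
the detection is exclusive to the tagged purification or the tagged/control
spectral-count ratio is at least 3-fold, and a protein is accepted with
support in at least 2 of the 4 tag conditions -- to the published 34-row
ratio matrix (bait row included).

Finding: all 33 non-bait rows are accepted; the bait itself qualifies in 3
conditions but is flagged and excluded from the interactor count.

Writes results/table2_calls.tsv.
"""

from pathlib import Path

from insitap.consensus import accepted_interactors, call_interactors, write_call_report
from insitap.fixtures import load_fixture

OUT = Path(__file__).resolve().parent.parent / "results"


def main():
    table, genes, conditions = load_fixture("table2_ratios")
    calls = call_interactors(table, genes=genes, conditions=conditions)
    accepted = accepted_interactors(calls)

    OUT.mkdir(exist_ok=True)
    write_call_report(calls, OUT / "table2_calls.tsv", conditions=conditions)

    bait = next(c for c in calls if c.is_bait)
    print(f"rows called: {len(calls)} ({sum(c.is_bait for c in calls)} bait)")
    print(f"accepted interactors: {len(accepted)}")
    print(f"bait {bait.gene}: qualifies in {bait.qualifying_conditions} conditions (excluded)")
    support = {}
    for c in accepted:
        support[c.qualifying_conditions] = support.get(c.qualifying_conditions, 0) + 1
    for k in sorted(support):
        print(f"  supported by {k} conditions: {support[k]} proteins")
    print(f"wrote {OUT / 'table2_calls.tsv'}")


if __name__ == "__main__":
    main()
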