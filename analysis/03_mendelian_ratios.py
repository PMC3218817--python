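"""Genotype-ratio analysis of the two heterozygote crosses.

For each cross (large NTAP tag, smaller NSC tag) the script reports
per-class percentages of genotyped pups and a Pearson chi-square
goodness-of-fit against the 1:2:1 Mendelian expectation.

Finding: the NSC cross is consistent with 1:2:1 (chi-square 5.19, df 2,
p = 0.075), while the NTAP cross deviates strongly (chi-square 21.82,
p < 0.001) -- homozygous pups are almost absent, consistent with loss of
function of the heavily tagged allele.

Writes results/mendelian_tests.tsv.
"""

from pathlib import Path

from insitap.fixtures import load_fixture
from insitap.mendel import class_percentages, pearson_gof

OUT = Path(__file__).resolve().parent.parent / "results"


def main():
    crosses = load_fixture("table1_genotypes")
    OUT.mkdir(exist_ok=True)
    report = OUT / "mendelian_tests.tsv"
    with open(report, "w") as fh:
        fh.write("cross\ttotal\tpercentages\tchi_square\tdf\tp_value\tmendelian_at_0.05\n")
        for cross, counts in crosses.items():
            pct = class_percentages(counts)
            res = pearson_gof(counts)
            verdict = "yes" if res.pvalue > 0.05 else "no"
            fh.write(
                f"{cross}\t{counts.total}\t{'/'.join(map(str, pct))}\t"
                f"{res.statistic:.2f}\t{res.df}\t{res.pvalue:.2e}\t{verdict}\n"
            )
            print(
                f"{cross}: n={counts.total}, wt/het/hom = "
                f"{pct[0]}% / {pct[1]}% / {pct[2]}%, "
                f"chi-square = {res.statistic:.2f} (df {res.df}), p = {res.pvalue:.3g} "
                f"-> {'Mendelian' if res.pvalue > 0.05 else 'non-Mendelian'}"
            )
    print(f"wrote {report}")


if __name__ == "__main__":
    main()
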