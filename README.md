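# insitap — in silico tandem affinity purification for multi-tag AP-MS

Affinity purification–mass spectrometry (AP-MS) recovers the binding
partners of a tagged bait protein, but any single tag's purification
chemistry both misses true interactors and enriches its own background.
Physically chaining two purifications (tandem affinity purification) trades
that background away for yield. `insitap` implements the *in silico*
alternative: run independent single-tag purifications — each with a matched
wild-type control — and intersect the results computationally.

The package was built around a four-tag purification series of the mouse
pluripotency factor Oct4 (Pou5f1), tagged at its endogenous locus with CBP,
FLAG, HIS and S tags, and includes the genotype-ratio statistics used to
check that a tag does not break the bait's in vivo function.

## The calling rule

For protein $i$ in tag condition $c$, let $t_{ic}$ and $n_{ic}$ be pooled
spectral counts in the tagged and control purifications. The per-condition
evidence is tri-state:

- **exclusive** (`Exc`): $t_{ic} > 0$ and $n_{ic} = 0$;
- **ratio**: $t_{ic}/n_{ic}$ when both are positive;
- **not detected**: $t_{ic} = 0$ (blank cell).

Condition $c$ *qualifies* when the detection is exclusive or the ratio is at
least the fold threshold $f$ (default $f = 3$, inclusive). A protein is
accepted as an interactor when it qualifies in at least $k$ of $n$
conditions (default $k = 2$, $n = 4$); the bait itself is flagged and never
counted. Genotype ratios are tested with Pearson's
$X^2 = \sum (O_j - E_j)^2 / E_j$ against a 1:2:1 Mendelian expectation on
$k - 1$ degrees of freedom.

## Worked example

Calling interactors from the packaged published ratio matrix (34 rows,
bait included):

```
$ python analysis/01_call_interactors.py
rows called: 34 (1 bait)
accepted interactors: 33
bait Pou5f1: qualifies in 3 conditions (excluded)
  supported by 2 conditions: 32 proteins
  supported by 3 conditions: 1 proteins
```

Every non-bait row qualifies in at least two of the four tag conditions, so
the default caller accepts all 33 candidate interactors; only one protein
(Fubp3) is supported by three conditions, which is why multiple tags were
needed in the first place. The Mendelian check on the two heterozygote
crosses:

```
$ python analysis/03_mendelian_ratios.py
NTAP: n=73, wt/het/hom = 34.2% / 64.4% / 1.4%, chi-square = 21.82 (df 2), p = 1.83e-05 -> non-Mendelian
NSC: n=148, wt/het/hom = 27.7% / 55.4% / 16.9%, chi-square = 5.19 (df 2), p = 0.0747 -> Mendelian
```

The large NTAP tag nearly eliminates homozygous pups (1 of 73 instead of
the expected ~18), while the smaller NSC tag segregates normally — the tag
choice matters for bait function, not just for purification.

The other drivers: `analysis/02_overlap_novelty.py` classifies the 33
interactors against a prior FLAG-purification list (3 known, 30 novel), and
`analysis/04_simulation_benchmark.py` scores the caller on synthetic
experiments with known ground truth (see `docs/methods.md` for what the
generator does and does not emulate).

There is also a CLI over the same library:

```
insitap call --ratios src/insitap/data/table2_ratios.tsv --out calls.tsv
insitap simulate --seed 7 --out simdir/
insitap mendel --counts 41,82,25 --ratio 1:2:1
insitap run --config pipeline.yaml
```

## Layout

- `src/insitap/` — library: count matrices and TSV dialects (`matrix`),
  tri-state enrichment and qualification (`enrichment`), dual-engine
  identification consensus (`identification`), the k-of-n caller
  (`consensus`), the synthetic generator and scoring (`simulate`),
  list algebra (`lists`), genotype statistics (`mendel`), orchestration
  (`pipeline`) and the CLI (`cli`).
- `analysis/` — numbered narrative drivers writing tables under `results/`.
- `docs/methods.md` — model, assumptions, parameter defaults, limitations.
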