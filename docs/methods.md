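# Methods

## The interactor-calling procedure

`insitap` models the analysis half of a multi-tag AP-MS study. The
measurement unit is the spectral count: the number of MS/MS spectra assigned
to a protein in one purification sample, a semi-quantitative abundance
proxy. Each tag condition contributes a tagged-line purification and a
matched wild-type control purification that captures resin- and
buffer-specific background. Gel lanes are cut into fractions (five by
default) that are measured separately and summed ("pooled") before any
ratio is formed; pooling conserves per-protein totals.

Per condition the evidence is deliberately tri-state rather than numeric:

| state | definition | table cell |
|---|---|---|
| exclusive | tagged > 0, control = 0 | `Exc` |
| ratio | both > 0; value = tagged/control | e.g. `3.0` |
| not detected | tagged = 0 | blank |

No pseudocounts are added: a zero-control detection is a qualitatively
distinct observation at low counts, and collapsing it to an infinite or
pseudocounted ratio would both distort the arithmetic and break round-trips
through published ratio tables. Ratios are kept at full precision
internally and formatted half-up to one decimal only at output.

A condition **qualifies** if the state is exclusive, or the ratio is at or
above the fold threshold (default 3.0, inclusive — a published row is
retained at exactly 3.0, fixing the boundary). A protein is **accepted**
with qualifying support in at least `k_min_support` of the conditions
(default 2 of 4). The bait is matched by identifier or gene symbol, flagged,
and excluded from the interactor count. The rule is a deterministic filter,
not a hypothesis test, so no multiple-testing correction applies; missing
conditions contribute zero support (no imputation).

Upstream of counting, the identification consensus keeps only proteins
whose best identification probability reaches the threshold (default 0.95,
inclusive) in **both** of two independent search engines. Duplicate records
per protein collapse to their maximum probability. Probabilities are taken
as given; database search and protein inference are out of scope. The
consensus is applied per pooled sample.

## Genotype-ratio statistics

Offspring of a heterozygote × heterozygote cross are expected to segregate
1:2:1 (wild-type : heterozygous : homozygous). Observed genotyped counts
are tested with Pearson's goodness of fit, X² = Σ (O − E)²/E on k − 1
degrees of freedom, expected counts being the total times the normalized
ratio weights. The p-value is the upper chi-square tail, computed with the
regularized upper incomplete gamma function Q(df/2, X²/2); the unit tests
cross-check it against `scipy.stats.chisquare` as an independent route. No
continuity correction is applied (three classes, df 2) and deaths before
genotyping are not modelled. Class percentages are rounded half-up to one
decimal for display; comparisons use unrounded values.

## List comparison

Interactor lists are compared as sets of gene symbols after normalizing
case to the mouse convention (first letter upper, rest lower). Matching is
exact; no alias or orthology resolution is attempted, so cross-scheme
identifier reconciliation is the caller's responsibility. Venn partitions
report all 2ⁿ − 1 disjoint regions of two or three lists; novelty
classification marks a gene known if any prior list contains it.

## The synthetic generator

`simulate_experiment` produces one tagged/control pair per condition
(replicates are not modelled; the study design it emulates ran one
purification per tag), each split into `n_fractions` independent fraction
columns whose means sum to the stated per-sample mean. Counts are Poisson;
an optional negative-binomial dispersion (off by default) adds
over-dispersion for robustness experiments. Per pooled sample:

| protein class | tagged mean | control mean |
|---|---|---|
| background contaminant | `bg_mean` | `bg_mean` |
| interactor, capturing condition | `bg_mean × enrich_factor` | `leak_mean` |
| interactor, non-capturing condition | `leak_mean` | `leak_mean` |
| bait | `bait_mean` | `leak_mean` |

Whether a condition can capture an interactor is drawn once per experiment
(Bernoulli `capture_prob` per interactor × condition) and returned in the
ground truth, reproducing the central phenomenon that different tags
recover different interactor subsets. Defaults are scaled to the low-input
regime the package targets: `bait_mean = 11` spectra (the bait signal
observed from 400 µg of nuclear extract), `bg_mean = 4`, `leak_mean = 0.2`
(frequent zero controls), four conditions, five fractions, capture
probability 0.5. Identifiers are synthetic (`BAIT`, `INT001`, `BG0001`);
no real gene symbols appear in generated data.

What the generator does **not** emulate: correlated background abundance
between tagged and control runs of the same protein, sample-depth
variation, peptide-level identification error, shared peptides between
proteins, and replicate purifications. Passing benchmarks on this generator
therefore show that the caller implements its rule correctly and recovers
strongly enriched proteins under independent Poisson noise — not that the
rule's error rates transfer to real AP-MS data.

### Benchmark behaviour worth knowing

In the strong-capture benchmark regime (100 background proteins at
`bg_mean = 4`, 20 interactors, capture probability 0.9, 20-fold enrichment,
`leak_mean = 0.1`, 30 seeds), the default caller's mean recall is ≈ 1.0 but
its mean precision plateaus near 0.74. This is a property of the rule at
low counts, not an implementation artifact: with independent Poisson(4)
tagged and control counts, a background protein qualifies in a single
condition with probability ≈ 0.11 (≈ 0.018 from a zero control with a
positive tagged count, ≈ 0.09 from ratio ≥ 3), so ≈ 6% of contaminants
clear the 2-of-4 consensus. `analysis/04_simulation_benchmark.py` measures
this directly. Real studies blunt the effect because background abundance
is correlated between the tagged and control runs of the same prep, a
correlation the generator intentionally leaves out of its independence
assumptions.

## Numerical and design choices

- Rounding is half-up (`decimal.Decimal`, applied to `repr(x)` to avoid
  binary-float artifacts), matching how the published tables print.
- Between-sample normalization is available (`normalize=True` rescales
  ratios by control/tagged sample depth) but off by default; published
  spectral-count ratio tables are computed on raw counts.
- Blank ratio-table cells parse as not-detected whether they mean "no
  spectra" or "below the identification filter"; the two are
  indistinguishable downstream and contribute no support either way.
- `evaluate_calls` reports precision 1.0 (flagged degenerate) when nothing
  is accepted, keeping sweeps over harsh thresholds well-defined.
- Pipeline runs are deterministic under a fixed seed; the run log records
  every threshold, the seed, and per-stage protein counts so the filter
  cascade is auditable.

## Limitations

- The caller is a deterministic filter; it assigns no interaction
  confidence score and is not a replacement for model-based AP-MS scoring
  on designs with replicates.
- Enrichment uses pooled-lane totals; per-fraction evidence is discarded
  after pooling.
- The packaged prior-study list contains only the overlapping genes, so
  cross-study comparisons beyond that overlap require user-supplied lists.
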