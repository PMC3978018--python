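# Methods

## The score

Each gene in a cohort is summarized by exact alteration counts: `A`
amplified samples (gene-level GISTIC value ≥ +2), `D` deleted samples
(≤ −1, i.e. heterozygous plus homozygous loss by default), `O`/`U`
over-/under-expressed samples (expression z beyond ±`z_thr`,
boundary-inclusive), `M` methylated samples, and `ns` nonsense
mutations. Per platform, `T_cnv`, `T_exp`, `T_met` count the samples
with a non-missing value for that gene — missingness is preserved at
load and never imputed, so "informative sample" totals are gene-specific.

The oncogenic and suppressive components are weighted sums,

    So = i_A·A + i_O·O
    Ss = i_ns·ns + i_met·M + i_D·D + i_U·U

and the score is `s = log2(So/Ss)` with clamp-to-1 guards: if one
component falls below 1 it is replaced by 1 (giving `−log2(Ss)` or
`+log2(So)`), and if both are below 1 the score is 0. The guards use a
boundary at ≥ 1, which is the unique convention making `s` continuous
where a component crosses 1 and consistent with "both below 1 maps to
0". Working on raw counts (rather than frequencies) is what makes the
guard threshold of 1 meaningful: one weighted alteration event is the
smallest quantum of evidence. Two alternative normalization modes are
provided and recorded in every output — `coverage_adjusted` rescales
each platform term by `N_cohort/T_platform` (terms with `T = 0`
contribute 0; the mutation term has no informative total and stays
unscaled), and `frequency` uses per-platform fractions (`ns/N_cohort`
for mutations). Under `frequency` almost every component is below 1, so
nearly all genes fall into the guard regimes; it is included for
completeness, not as a default.

Properties the test suite enforces: antisymmetry (swapping the two
weighted loads negates `s` in the ratio regime), monotonicity in each of
the six counts, continuity at the guard boundaries, and the exclusivity
reward (for a fixed total weighted load, one-sided evidence gives |s| at
least as large as any split).

## Index weights

The default profile `paper2014` is `i_ns = 5`, `i_A = i_O = i_D = i_U =
0.5`, `i_met = 0`. Nonsense mutations carry the large weight because a
premature stop almost always abolishes protein function, so even a few
events are strong suppressor evidence; methylation is disabled in the
default profile (its weight, not its plumbing — setting `i_met > 0`
re-enables it). `grid_search_indexes` re-derives this choice on data:
scenarios are ranked by the sum over cohorts of the number of simulated
gene sets whose extreme count matches or beats the benchmark's (smaller
= more consistently enriched), with ties keeping input order.

## Alteration calling choices

- CNV categories follow the gene-level GISTIC convention: homozygous
  deletion ≤ −2, deletion (−2, −1], neutral (−1, +1), gain [+1, 2),
  amplification ≥ +2. `D` includes heterozygous losses and `A` excludes
  gains by default; both rollups are config switches
  (`include_hetloss_in_D`, `include_gain_in_A`).
- `z_thr` defaults to 2.0 (the cBioPortal-era outlier convention),
  boundary-inclusive and symmetric.
- Nonsense mutations are records whose `variant_class` is in
  {`Nonsense_Mutation`, `nonsense`, `stop_gained`} (extensible). In
  `cohort` mode a sample contributes at most one event per gene; in
  `external_catalog` mode records are counted as-is, because catalog
  totals cannot be deduplicated against cohort membership. Group
  comparisons force `cohort` mode, since catalog counts cannot be
  restricted to a sample subgroup.
- Methylation enters as a precomputed binary matrix; a beta-threshold
  helper (`beta ≥ 0.7`) exists but is never applied implicitly.

## Benchmarking

`monte_carlo_enrichment` draws same-size gene sets uniformly without
replacement from the scored universe and counts extreme genes per set.
The estimator is the plain exceedance fraction `#(sim ≥ real)/n_sim`,
rendered as `< 1/n_sim` when no simulated set reaches the real count; a
`plus_one` flag switches to `(k+1)/(n+1)`. Because the count in a
uniform draw is exactly hypergeometric, the closed-form tail serves as
an independent oracle in the tests (agreement within 3 standard errors
at n_sim = 100,000) and the estimator is verified super-uniform under
exchangeable-null benchmarks.

`predictive_values` follows the resampled-confusion design: positive
sets drawn from the benchmark (beyond threshold → TP, else FN), negative
sets from the universe minus the benchmark (beyond threshold → FP, else
TN), with PPV = tp/(tp+fp) and NPV = tn/(tn+fn) formed from mean counts.
A zero denominator yields a missing value, never 0. Note that when
nothing is extreme, tp = fp = 0 gives an undefined PPV and NPV = 0.5
(all drawn positives become FN), which follows directly from the
formulas.

Extreme thresholds come in two rules: `fixed` (±value, default ±2,
strict inequalities) and `zscore` (mean ± value·SD of the cohort's score
distribution, sample SD with ddof = 1; a degenerate sd = 0 distribution
is an explicit error).

## Cohort comparison

Survival quartiles use the linear-interpolation empirical 25th/75th
percentiles; Q1 is time ≤ the lower boundary, Q4 time ≥ the upper, with
samples tied on a coinciding boundary excluded from both groups and a
hard error when ties collapse a group. Censoring is ignored by default
(samples with missing time are simply excluded); restricting to deceased
patients is the caller's filter.

Group scoring is literally cohort scoring on the restricted sample set —
counts and informative totals are recomputed per group, and a
restriction oracle in the tests asserts equality with a from-scratch
cohort built from those samples.

Discordance between two groups is classified as: `threshold_dual` when
the scores have opposite signs and both magnitudes strictly exceed 2.5
(the stringent cross-tumor criterion); `sign_opposite` when signs are
opposite, both magnitudes are ≥ 1.0 and at least one is ≥ 2.0; otherwise
`concordant`. The `sign_opposite` band was an open design point: the
lower cutoff of 1.0 keeps near-zero noise flips out while admitting the
canonical asymmetric flip pattern (e.g. +3.0 in one group against −1.4
in the other); all three cutoffs are parameters. The cross-tumor screen
itself uses only the strict |s| > 2.5 two-cohort rule and is symmetric
in cohort order.

`top_k_scatter` ranks by score with lexicographic gene-symbol
tie-breaks, so rank-k ties resolve deterministically; sides with fewer
than k genes shrink with a warning.

## Synthetic cohorts

The generator emulates the statistical shape of portal-style cohort
matrices: per-gene per-sample Bernoulli alteration draws, per-platform
missing-cell masks, a mutation table with nonsense and missense records,
and a clinical table with survival times and categorical covariates.
Effect values land comfortably past the calling thresholds (amplified
cells uniform on [2, 4], homozygous-deleted on [−4, −2], outlier |z|
uniform on [z_thr + 0.5, z_thr + 3]); neutral CNV is uniform on
(−0.9, 0.9) and neutral z is standard normal *truncated* just inside the
calling threshold. The truncation is deliberate: it makes the realized
expression calls coincide exactly with the configured Bernoulli draws,
so the recorded truth table is exact and expression background is
controlled solely by the explicit background rates. Default background
rates (fraction of samples per gene) are amplification/deletion 0.01
each, over-/under-expression 0.02 each, nonsense mutation 0.002,
methylation 0.01 — chosen once as plausible per-gene event rates for
solid-tumor cohorts of a few hundred samples.

Reproducibility: one RNG stream per platform per cohort, derived from
the master seed, so adding a platform never perturbs another platform's
draws; identical configs produce byte-identical files. One exception:
the silenced-suppressor overlay (methylated AND under-expressed cells
co-occurring) is drawn on the methylation stream and stamped onto the
expression matrix, because cross-platform co-occurrence cannot live in a
single stream.

What the generator does **not** emulate: gene–gene correlation
(chromosome arms moving together, co-amplified neighbors),
mutation-signature structure, segment-level copy-number geometry, or
overdispersed expression noise. Consequently, passing recovery and
calibration tests shows the pipeline is correct and well-calibrated
under independent-gene noise; it does not show that score thresholds
transfer to real cohorts, where locus-level correlation inflates the
extreme tail (genes co-amplified with a driver score high together).

## Problem sizes in the test suite and acceptance script

The statistical checks run at sizes chosen to give each test resolution
while staying lightweight: counting equivalence over 50 seeded cohorts
of 100 genes × 100 samples; enrichment-oracle agreement at n_sim =
100,000 over 10 seeds; calibration over 200 null worlds of 300 genes ×
60 samples with elevated background rates (so the score distribution has
enough dispersion for z-score thresholds to bite and the discrete
p-values enough resolution near 0.05); recovery over 100 seeded
200-sample cohorts with planted effect frequency 0.4; and a four-cohort
acceptance study of 600 genes with a 138-gene benchmark, 10,000
simulated sets and 1000×50 predictive-value resampling. Recovery and
separation worlds use zeroed background rates so that the planted/null
partition is exact and predictive values have a well-defined truth;
calibration worlds deliberately do the opposite.

## Known limitations

- The raw-count components make `s` depend on cohort size: the same
  alteration frequency yields larger |s| in larger cohorts. Comparing
  groups of very different size is best done with `coverage_adjusted`
  mode or equal-size subsampling.
- A single nonsense mutation contributes 5 to `Ss` under the default
  profile, so in mutation-rich cohorts many genes clear the fixed −2
  threshold; the z-score-normalized thresholds adapt to this, the fixed
  pair does not.
- PPV/NPV depend on the benchmark list's composition; a list containing
  genes irrelevant to the analyzed tumor types understates both.
- No index exists for activating (missense) mutations; the score cannot
  fully capture oncogenes driven by point activation.
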