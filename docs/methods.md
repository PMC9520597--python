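# Methods

This note documents the statistical machinery in chemosig, the choices made
where the design was genuinely open, and what the synthetic-data experiments
do and do not demonstrate.

## Survival primitives

**Kaplan–Meier.** The product-limit estimator
`S(t) = Π_{t_i ≤ t} (1 − d_i/n_i)` over distinct death times; samples
censored at a death time count as at risk at that time. With no censoring it
reduces exactly to the empirical survivor function (a test invariant).

**Log-rank.** The two-group Mantel–Haenszel form with hypergeometric
variance and 1 df; the reported `direction` is the sign of observed-minus-
expected deaths in the designated group. Screening needs the test over
thousands of median-split group assignments sharing one set of follow-up
times, so the implementation is vectorized over assignments (one pass over
the sorted risk sets); a 5,000-gene screen at n = 300 takes well under a
second. The scalar path is cross-checked against lifelines to 1e-9 and, on
all ≤8-sample instances, the exact permutation p induced by our statistic is
identical to the one induced by lifelines'. Note the exact permutation law
at such sizes is discrete (atoms of `2/C(n,k)`), so an asymptotic chi-square
p can track it only in the tail; the tests bound that gap explicitly.

**Horizon tables.** At horizon `h`, a sample is dead iff its event occurred
at `t ≤ h`; everyone else — including samples censored before `h` — counts
as alive. This is the convention that keeps group totals constant across
horizons, matching published tables of this form; it undercounts true deaths
among the early-censored and is reported as a descriptive table, not an
estimate. Survival percentages are rounded half-up to 2 decimals. Horizons
default to 365/1095/1825 days.

**Continuity-corrected chi-square.** `X² = Σ max(|O−E|−0.5, 0)²/E` on the
2×2 counts. The floor at zero matters: SciPy's Yates correction shifts each
observed count half a unit toward its expectation even when `|O−E| < 0.5`,
which cannot produce the 0.00 values published tables show for
near-independent tables. Our statistic reproduces 11 of the 12 published
treated-vs-untreated horizon cells to 2 decimals; the remaining cell
(printed 0.45) is not reproducible from its printed counts under either the
corrected (0.00) or uncorrected (0.05) convention and is documented rather
than matched. Star annotations use the conventional 0.05/0.01/0.001 map.

## Screening

Genes are dichotomized at their cohort median with ties going low; the
screen is therefore invariant to any monotone transform of a gene's values.
Genes with more than half their values tied at the median (or an empty
side) are *skipped*, not force-split. Significance uses the raw per-gene
cutoff α = 0.01 with **no multiplicity correction** — the screen reproduces
a published selection rule in which the panel is the object of interest and
downstream evaluation is the control, so the α-level false-positive load is
intentional and quantified by the null-calibration test. Records with zero
follow-up and no event are excluded before screening (logged). Direction:
`pro` when the high-expression group saw fewer deaths than expected, `con`
otherwise.

## Signature score and evaluation

Per-gene z-scores use the sample standard deviation (n−1); zero-variance
genes map to all-zero rows. ZSCORE_Pro and ZSCORE_Con are **means** (not
sums) of member-gene z-scores, making the score invariant to panel-size
imbalance. Z-scores are computed **within the evaluated cohort** (the
treated samples of a grid cell); when the evaluation cohort is also the
screening cohort this reproduces the in-sample optimism of the original
design faithfully — it is documented, not removed, and the null-cohort
acceptance check quantifies that a panel carried to an independent cohort
shows no spurious separation.

Benefit/futile labels split treated samples at the median of *observed*
time, censored or not — the phrasing "longer survival times" over a mixed
dead/censored cohort forces this; ties at the median are futile. The AUC is
rank-based with half-credit for ties (Mann–Whitney), delegated to
scikit-learn and verified against brute-force pair counting. Grid cells
report NA when fewer than 6 labeled samples are present (total, not per
class) or a label class is empty.

## Deconvolution

The reference is the per-gene mean profile of each cell type, built after
the cell QC filter (feature count in [200, 2500] inclusive, mitochondrial
fraction strictly below 0.15 — the bounds read literally). Proportions
solve `min_w ‖b − Rw‖², w ≥ 0` (scipy NNLS) on the gene intersection,
then renormalize to the simplex, which also grants scale invariance in the
bulk profile; an all-zero solution is an error, and fewer than 2 shared
genes per type triggers a warning. This estimator is the package's own
design for the reference-based decomposition stage: the downstream
proportion-comparison logic is estimator-agnostic and the test surface is
recovery of known synthetic truth (noiseless mixtures exact to 1e-6; mean
absolute error < 0.05 at 5% noise with 5 types and 200 genes). Group
comparisons use the two-tailed **Welch** (unequal-variance) t-test — the
published analyses say only "two-tailed t-test", and Welch is the safer
default for proportion data with unequal group sizes.

## Synthetic cohorts

The generator's defaults are the package's study conditions, fixed once:

| parameter | default | rationale |
|---|---|---|
| n_samples × n_genes | 300 × 5,000 | realistic treated-cohort size; reduced protein-coding transcriptome |
| n_pro / n_con | 20 / 20 | planted-panel size used by the recovery experiments |
| hazard_ratio | 3 | per-gene high-vs-low effect; Pro genes use its reciprocal |
| baseline_hazard | ln2/500 per day | baseline median survival 500 days, plausible for advanced gastric cancer |
| censoring_rate | 4e-4 per day | independent exponential censoring, ≈30% censored under the defaults |
| gene means, noise | N(3, 1) ± N(0, 1) | log-scale normalized expression (the normalization scale of public cohorts is unstated; log scale is assumed and documented here) |
| nb_dispersion | 2 | single-cell gamma-Poisson counts, var = μ + μ²/r |
| qc_violation_rate | 0.2 | share of cells planted outside the QC bounds |
| bulk_noise_fraction | 0.05 | bulk-mixture noise sd as a fraction of mean reference signal |

Survival is exponential (constant hazard) for closed-form checkability, with
`log h = log h₀ + Σ_g β_g·1[expr_g > median_g]` and `β = ±ln(hazard_ratio)`
on planted genes — the hazard acts on the *dichotomized* expression,
mirroring the median classifier used in screening. Expression is Gaussian
around per-gene means and independent across genes.

**What this generator does not emulate** — and the consequences:

- *No co-expression among planted genes.* Real Pro/Con programs (immune,
  ECM) are strongly co-expressed; here each planted gene carries an
  independent ±ln(HR) hazard term. With 40 independent planted genes the
  per-sample log-hazard has a standard deviation of √(40·0.25)·ln 3 ≈ 3.5,
  so any single gene explains at most 1/√40 of the hazard ordering. This
  caps the per-gene log-rank z near 2.7 at n = 300 regardless of the hazard
  ratio: measured recovery of a 20+20 planted panel is ≈ 0.39 at α = 0.01
  (direction errors zero), and no analysis choice can raise it — the
  information is not in the data. Recovery of sparse panels (≤5 per side)
  or single genes exceeds 0.9 as the per-gene power calculation predicts.
- *Continuous-score vs indicator mismatch.* The z-score signature averages
  continuous expression while the generator's hazard responds to the median
  indicator (correlation ≈ 0.8 between the two), and event times add
  exponential noise; together these cap the end-to-end benefit/futile AUC
  near 0.83–0.86 even for an oracle panel, versus ≈ 0.5 on null cohorts.
  Passing separations on this generator therefore demonstrate correct
  machinery and calibration, not the ceiling attainable on real cohorts
  where co-expressed programs make signatures stronger per gene.
- No batch structure, library-size artifacts, doublets or dropout in the
  single-cell reference; QC metrics are simulated per cell solely to
  exercise the filter.

## Numerical conventions

Rounding of reported percentages and statistics is half-up (not banker's).
NNLS tolerance is scipy's default; proportion vectors are validated to sum
to 1 within 1e-9 on input and 1e-6 on output. NA is emitted literally as
`"NA"` in grid TSVs. All generators draw from `numpy.random.default_rng`
seeded by the configuration, and identical configurations reproduce outputs
byte for byte (the run manifest records configuration and versions, never
timestamps). Problem sizes in the acceptance script (100 screening seeds,
20 null-cohort seeds, 50 bulk mixtures) were chosen to keep each quantity's
Monte-Carlo error well below its decision margin.
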