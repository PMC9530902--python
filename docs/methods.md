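# Methods

## The trade-off model

Within a medium, strains of every genotype — wild type, genome-reduced,
MMR-deficient mutator, genome-reduced mutator — fall on a common line in
(growth rate, log mutation rate) space:

    log10(M_i) = log10(M_inf) + alpha * mu_i

with `mu_i` in h⁻¹ (natural-log growth rate) and `M_i` in bp⁻¹ division⁻¹.
`M_inf` is the maximal mutation rate as growth approaches zero and
`alpha < 0` the coupling slope; both are medium-dependent, genotype-
independent parameters. Defaults carried by `MediumSpec`:

| medium | alpha | M_inf (bp⁻¹ div⁻¹) | mu range (h⁻¹) |
| --- | --- | --- | --- |
| LB  | −9.5  | 1e-3 | 0.40–0.80 |
| MAA | −12.6 | 4e-4 | 0.25–0.60 |
| M63 | −12.8 | 7e-6 | 0.10–0.45 |

The base-10 form is used throughout: the slope and intercept magnitudes
above are mutually consistent only on the log10 scale over these growth
and mutation ranges. Growth-rate ranges are a design choice (units are
h⁻¹; sources for the system report only relative rates): they are set so
generated mutation rates span ~1e-10 to 1e-7 bp⁻¹ division⁻¹, the decade
range over which fluctuation assays of nalidixic-acid resistance are
informative. `fit_tradeoff` is unweighted OLS of log10(M) on mu, pooled
over all collections — M as response, since M_inf is defined as the mu→0
intercept. Noiseless inputs are reproduced exactly; the companion Pearson
r and p come from the same pairs.

## Synthetic data generator

The generator emulates the study's structure, not any particular measured
values:

- **Panels.** Three collections with their characteristic genotypes: MDS
  (parent MDS42, genome-reduced; derivatives additionally MMR/proofreading
  deficient), KHK (parent W3110; derivatives genome-reduced), MG (parent
  MG1655; derivatives mutators). Default sizes 14/10/10. The
  four-level genotype class is a deterministic function of the two binary
  flags.
- **Rates.** Each strain has one latent vigor u ∈ (0,1) reused across
  media: the parent draws from U(0.6, 1), derivatives inherit the parent's
  vigor times U(0.5, 1) and times fixed handicaps (×0.75 if genome-reduced,
  ×0.65 if MMR-deficient), so derivatives always grow slower than their
  parent and growth orders LB ≥ MAA ≥ M63 per strain; both properties
  drive the cross-media rate correlations and the fold-change signatures
  downstream. log10 M gets i.i.d. Gaussian noise (default SD 0.2 decades
  — a plausible strain-to-strain deviation from the law; the sources give
  no value). What this does **not** emulate: medium-specific scatter
  shapes, the discontinuous structure of the MAA region seen in measured
  landscapes, day effects, or correlated growth/mutation noise — so
  classification accuracies here are upper bounds on what measured data
  would give, and the linear/RBF gap in particular is compressed because
  the generated media are almost linearly separable.
- **Fluctuation assays.** Mutation events per culture ~ Poisson(m) with
  m = M · target_size · N_final; each event's clone expands to
  ⌊N_final/x⌋ cells, x ~ U(1, N_final) — the 1/x² clone-size law, i.e.
  clone sizes P(k) = 1/(k(k+1)). This process simulator is kept
  deliberately independent of the analytic pmf so the two can cross-check
  each other (they agree by chi-square at m ∈ {0.5, 1, 4} over 1e5
  cultures). m = 0 returns all-zero counts; negative rates are rejected.
- **CFU plates.** Counts ~ Poisson(N_final × dilution), n plates per
  dilution.
- **OD curves.** Logistic OD(t) = K·od0·e^(mu t) / (K + od0·(e^(mu t)−1))
  plus Gaussian read noise truncated at 0. Defaults: od0 0.01, capacity
  1.0, reads every 30 min for 48 h, noise SD 0.002. The 48 h record
  matters: slow growers (mu ≈ 0.1 h⁻¹) must reach plateau within the
  record for the growth estimator's density extrapolation to be stable.

All generation is seeded; stage seeds derive from the global seed by a
stable CRC32 hash of (seed, stage tags), so identical configs are
bit-reproducible and editing one stage leaves the others' streams intact.

## Mutation-rate estimation

The Lea–Coulson pmf is computed by the Ma–Sandri–Sarkar recursion, which
is the Panjer recursion for a Poisson(m) number of clones with the
1/(k(k+1)) clone-size law:

    p_0 = e^(−m),   p_n = (m/n) · Σ_{j<n} p_j / (n − j + 1)

(The head terms at m = 1 are 0.36788, 0.18394, 0.10730, …; the truncated
mass approaches 1 like 1 − m/n_max, reflecting the heavy jackpot tail.)

`estimate_m_mle` maximizes the pmf likelihood in log-m by bounded scalar
search on (1e-4, 1e4), seeded at the P0 estimate when zeros exist or at
half the median count otherwise; counts beyond n_max (default 1500) are
lumped into the truncated tail mass. The 95% CI is the profile-likelihood
interval (log-likelihood drop of 1.92). All-zero samples sit at the
boundary: m̂ = 0 with one-sided upper bound −ln(0.05)/n from p₀ⁿ. The P0
estimator m̂ = −ln(zero fraction) is exposed as fallback/diagnostic and
lies inside the MLE's CI in ≳90% of 30-culture samples at m = 1.

Population size comes from the CFU plates after discarding colony counts
outside 10–500 (the reliability window); the estimate is the mean of
count/dilution over retained plates, with an explicit "no reliable plate"
error when the filter empties the set. Rates convert as
M = m̂ / (N_final · target_size); the effective nalidixic-acid target size
is not published, so `target_size_bp` (default 30) is a single constant
used identically by generator and estimator — absolute rates are
internally consistent rather than calibrated to the wet assay. Replicate
assays are combined as the arithmetic mean with SE over replicates (mean
vs median is unspecified in the sources; mean is the simplest unbiased
choice at N = 3–6).

In the pipeline, each condition's culture size is chosen so the expected
mutations per culture is ≈ 2 (clipped to [1e5, 5e9] cells), as an
experimenter would dilute to keep mutant counts countable; the chosen
N_final is then measured back through the simulated CFU assay rather than
assumed.

## Growth-rate estimation

Windowed log-linear fitting with three quality gates and a density
extrapolation:

1. every contiguous window of `window_points` (default 5) readings gets a
   least-squares line on ln(OD) (vectorized over windows);
2. a window qualifies if r² ≥ 0.95, its ln-residual RMS ≤ 0.05 (points on
   the line to within ~5%), and its mean OD is ≥ 10× the curve's read-noise
   floor (the smallest OD-scale windowed residual, i.e. the flattest
   stretch of the same curve) — the floor gate removes low-signal windows
   whose noise can masquerade as steep, clean growth;
3. because a logistic culture's local log-slope declines linearly with
   density, mu(1 − OD/K), the rate is the zero-density intercept of
   qualifying window slopes regressed on window mean OD, weighted by OD²
   (ln-noise variance ∝ 1/OD²). With fewer than three qualifying windows,
   or no density spread, the maximal qualifying slope is used directly.

A plain max-qualifying-slope rule was measured at +13% bias for slow
growers (noise-selected windows) and −7% for fast ones (logistic
flattening) under the default noise; the extrapolated estimator is exact
on pure exponentials and noiseless logistics and shows ≤1–2% bias across
mu ∈ {0.1, …, 0.7} at noise SD 0.002 with 6 wells. Blank subtraction
clamps at a 1e-3 OD floor so logs exist; a perfectly flat curve has rate
0 by convention. Replicates aggregate as mean ± SE over wells; wells with
no qualifying window are dropped, and an all-fail condition raises a
quality error naming the best r² seen.

## Prediction layer

**Encoding.** One row per (strain, medium): mu, log10 M, medium numeral
(LB 1, MAA 0, M63 −1), and a genotype covariate that is gr·md
("interactive") or gr+md ("additive") over the genome-reduction and
MMR-deficiency indicators.

**MLR.** statsmodels OLS with intercept; response log10 M on (mu, medium,
genotype) or mu on (log10 M, medium, genotype); adjusted R² and
per-coefficient two-sided t-tests, no multiple-testing correction. A
constant genotype column (interactive coding with no doubly disturbed
strains) is dropped and flagged as non-informative rather than raising;
any other constant or collinear predictor raises a singularity error
naming the columns.

**SVM.** scikit-learn SVC on the two quantitative features only, each
repeat: stratified 60/40 train/test split, z-scoring fit on the training
split (unscaled features would degenerate the RBF kernel: mu ~ 0.5 vs
log10 M ~ −8), inner stratified k-fold search over C (and gamma) in
{1e-3 … 1e2} by decades scored by macro-averaged recall, then test
accuracy from the confusion matrix. k is 5, reduced to the smallest
training-class count when a class (e.g. wild type, 2 strains) cannot fill
five folds. Both kernels are evaluated on identical splits (the sub-seed
excludes the kernel) so the linear/RBF comparison is paired. Five repeats
by default; a fixed-hyperparameter mode (linear C = 10 medium / 100
genotype; RBF C = 10, gamma = 1 medium / C = 100, gamma = 0.01 genotype)
reproduces final published settings for landscape drawing.
`decision_landscape` rasterizes a trained classifier over a
(mu, log10 M) lattice for region plots.

## Pipeline

`run_pipeline(RunConfig)` executes simulate → estimate (fluctuation +
growth) → rate-table assembly → trade-off fits → MLR (both responses ×
both modes) → SVM (both targets × both kernels) → report, logging one
structured line per stage and attributing any failure to its stage.
Degenerate configurations degrade explicitly rather than abort: a
single-medium run still fits that medium's trade-off but records the
medium classifier and medium-coded regressions as skipped, with reasons,
in the report. Reports carry recovery diagnostics (true vs fitted alpha
and M_inf per medium) whenever the run used synthetic truth. The default
run (34 strains × 3 media, 3 assay replicates × 30 cultures, 6 wells)
completes in well under a minute on one core.

## Known limitations

- Absolute mutation rates hinge on the unpublished mutational target
  size; only relative structure is comparable across studies.
- No phenotypic lag, differential mutant fitness, or plating-efficiency
  corrections in the fluctuation model; no Bayesian estimators.
- The growth module estimates only the maximal rate — no lag time or
  yield — and assumes logistic-shaped saturation when extrapolating.
- The generator's media are close to linearly separable in (mu, log10 M),
  so classifier accuracies (and the linear/RBF gap) should not be read as
  predictions for measured data.
- Wilcoxon signed-rank is used for media-shift tests (the test behind the
  published shift p-values is unnamed); the choice is recorded in the
  result metadata.
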