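# Methods

This note documents the statistical model behind `brainpad`, the assumptions
of the synthetic-cohort generator, the numerical choices, and the known
limitations. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The bias model and its inversion

Predicted brain age from an imaging model is treated as an affine function of
chronological age plus error:

    brain age = f_β(age) + ε,

with three candidate forms of f: a single global line (*marginal*, 2
coefficients), one line per modality (*by_modality*), or one per scanner
model (*by_scanner*); each can be fitted by OLS or by WLS with observation
weights equal to the inverse frequency of the observation's modality or
scanner, so every group contributes equally to the fit. The coefficient count
is always twice the number of *observed* levels — levels with fewer than
3 scans (2 parameters + 1 residual df) are flagged unfittable rather than
fitted.

The correction is the inverse of the fitted line at the record's level:

    corrected brain age = (brain age − β̂₀) / β̂₁.

Because it never reads chronological age it cannot inflate accuracy: it is an
affine map of the prediction, so corr(corrected, age) = corr(prediction, age)
exactly, and var(corrected) = var(prediction)/β̂₁² exactly. Records whose
modality/scanner level is absent from the fit use the unweighted mean
intercept and mean slope across fitted levels. The age-dependent alternative
(`age + brain age − f(age)`) is provided only as a diagnostic: under a
complete null with out-of-sample coefficients it still produces
corr(corrected, age) ≳ 0.87, and the acceptance suite reproduces that
inflation by simulation.

**Model selection.** Candidates are scored by the bias-corrected MAE on each
CV fold's evaluation sub-set, averaged across folds. Mean MAEs are compared
after rounding to one decimal; ties are broken by fewest coefficients, then
by lowest across-fold MAE standard deviation — simplest and most stable wins.
A candidate that cannot be fitted in some fold is dropped with a log entry.

One property of the selection criterion is worth spelling out: the
by-modality model wins only when between-modality *slope* differences
dominate. If one modality's slope is nearly flat, its per-modality inverse
correction amplifies noise by 1/slope and the corrected MAE explodes, so the
criterion correctly prefers the marginal model; a modality that flat is
better excluded from fitting altogether. The selection property test
therefore uses a large but non-degenerate slope gap (0.9 vs 0.45) as its
heterogeneous condition.

## Synthetic cohorts

Real clinical MRI archives are not shareable, so the generator produces
cohorts with the statistical structure such an archive has after prediction.

**Ages** are drawn from a normal distribution truncated to the configured
bounds (default 15–95 y) whose underlying (μ, σ) are solved numerically so
that the *truncated* mean and SD equal the targets (default 53.5 and 18 y);
by near-symmetry the median then also tracks the target. A zero target SD
degenerates to a point mass; infeasible targets raise a calibration error.

**Structure.** Each participant receives one sex (default ≈ 67% female, the
1039 F / 501 M ratio of a 1540-participant clinical cohort), one *home
scanner* drawn from the scanner table, and a subset of seven modalities by
independent inclusion with the configured prevalences; repetition counts
(1–4) are drawn per modality. Two modelling choices are deliberate:

- *Prevalences are per-participant inclusion probabilities*, not a
  distribution over modalities — participants must be able to carry several
  modalities or within-subject reliability would be undefined. Only the
  repetition distributions are required to sum to 1.
- *Scanner is a participant-level attribute*: clinical participants are
  scanned at a facility, and making the scanner a per-scan independent draw
  would let nearly every participant touch a held-out scanner, destroying
  the forced-test logic. A per-modality scanner lock (default: IR on
  Signa HDxt) emulates single-site modalities. The defaults are approximate
  marginal frequencies; the exact joint modality × scanner composition of
  any particular archive is configuration, not a package claim.

**Predictions** are `β₀ + β₁·age + offset_m + s_i + ε`, with defaults
β₀ = 15.2 y, β₁ = 0.7 (a typical regression-dilution severity for clinical
data), modality offsets of 0–2 y, a subject-level random effect s_i
(SD 3 y) shared across all of a participant's scans, and scan noise of
5–8 y by modality. One configurable *failure modality* (default T2wGRE:
intercept 40 y, slope 0.15, noise 8 y) emulates a modality the predictor
essentially cannot handle. A *null mode* instead trains an OLS learner of
age on 10 pure-noise features in an independent draw and evaluates it, so
null predictions carry no age signal but have the reduced-variance character
of a fitted learner, var ≈ (p/n)·var(age).

Per-slice predictions (scan value + i.i.d. Gaussian slice noise, aggregated
by the median across slices) are supported; the default emits scan-level
predictions directly (`slice_count = 0`) because the slice layer adds 80
columns per scan without changing any downstream statistic — the slice path
is exercised explicitly where it matters.

What the generator does **not** emulate: image content and quality, scanner
drift, non-linear bias shapes, age-dependent noise, missingness mechanisms
correlated with health status, or any correlation between modality
availability and age/sex. Passing tests therefore demonstrate correctness of
the statistical machinery under the stated generating model, not performance
claims about any real predictor.

## Data subdivisions

Splitting is participant-level throughout: a participant's scans never
straddle a boundary ("participant leakage"). Participants carrying a
forced-test modality or scanner are moved to the test set first; remaining
target proportions (default 71/12/17) are recomputed over the remainder as
residual target counts. The remainder is stratified on the Cartesian product
of sex, modality set, scanner set and 20-year age bin.

Within each stratum, ids are shuffled (seeded) and cut by largest-remainder
apportionment; because the Cartesian strata are mostly tiny, the fractional
residual of each stratum is *carried* into the next (Bresenham-style), which
keeps the global allocation proportion-faithful where naive per-stratum
rounding would systematically favour the largest split. Strata smaller than
the number of splits are reported in an aggregate warning, never silently.
CV folds (default k = 3) and the 63/37 bias/evaluation sub-split of each
held-out fold use the same machinery.

Distribution equality among splits is checked with pairwise two-sample KS
tests on participant-level age and χ² tests on sex, modality and scanner,
Bonferroni-corrected within each variable. The categorical tests count each
(participant, level) pair once: allocation is participant-level and repeat
scans share their participant's labels, so scan-level counts are clustered
and would inflate χ². With the default forced-test rules the modality and
scanner comparisons against the test set are *expected* to reject — rare
modalities exist only there by construction.

Observation-weight schemes for downstream training are provided: uniform,
1/(participant's scan count), and the latter additionally divided by the
scan-level prevalence of the scan's 20-year age bin and of its sex.

## Accuracy evaluation

**Constrained R².** R² = 1 − RSS/TSS with RSS taken against the identity
line (slope 1, intercept 0) and TSS about the mean of the *predictions*; a
perfect predictor gives 1, and poorly aligned predictions give negative
values. Constant predictions leave the statistic undefined (NaN, with a
warning).

**Repeated-measures bootstrap.** Each replicate resamples participants with
replacement and draws one repetition per sampled participant uniformly at
random (per modality; the pooled variant draws one repetition of every
modality a sampled participant carries). MAE, r and R² are computed per
replicate; the report gives across-replicate means and percentile intervals
at level 1 − α/m, with m defaulting to the number of rows in the emitted
table (Bonferroni). Replicate counts scale with the repetition and modality
multiplicity: base × N_r per modality and base × N_r × N_m pooled, with
base = 10,000 by default (reduced in tests and examples to keep runtimes in
seconds; CIs at base = a few hundred are already stable to the displayed
precision). Percentile intervals are used rather than BCa — simpler, and
adequate for the smooth statistics involved. Whether to resample
participants in addition to the repetition draw is a genuine choice; without
it no confidence interval exists, so both are done, seeded.

**Residual slope test.** `PAD ~ modality × age` by least squares over all
scans, with an omnibus F-test that every modality-specific slope is zero,
uncorrected per-modality t-tests as post-hoc, and a contrast on the mean
slope over a caller-chosen modality subset (typically excluding the failure
modality). Scans are deliberately treated as independent here — the test
mirrors a scan-level analysis whose degrees of freedom count scans — and the
result object carries a note recording that repeated measures are not
modelled.

**Mixed model on |PAD|.** `|PAD| ~ subject + modality + (1|subject)` fitted
by REML with a quasi-Newton optimizer (L-BFGS). The modality contrasts
against a reference (default MPRAGE) estimate within-subject differences in
absolute error; the "population" MAE estimate per modality is
⟨s_i⟩ + β_m (mean subject fixed effect plus the modality effect), and the
total is the mean of those over modalities. Two caveats are intentional and
documented rather than hidden. First, subject appears as both a fixed effect
and a random intercept; the model is fitted as stated, the random variance
is typically driven toward zero, and convergence status plus captured
warnings are part of the result. Second, the within-subject covariance of
repeated measures is carried by the random intercept (compound symmetry);
a fully unstructured residual covariance is not fitted. Contrast inference
uses normal-approximation intervals on the fixed-effect covariance. A
zero-residual (perfectly fitting) dataset short-circuits to the exact
least-squares solution with zero-width intervals, since the REML problem is
degenerate there.

## Reliability

Corrected PADs are reorganized into a participants × items matrix with one
item per (modality, repetition) pair, up to 4 repetitions. Dropping follows
a fixed order — participants with fewer than 3 observed items first, then
items more than 95% missing — because the reverse order can retain different
cells. The item covariance uses full pairwise deletion with pair-specific
means; pairs with fewer than two complete cases are excluded from both the
trace and the total. Cronbach's alpha is k/(k−1)·[1 − trace(C)/Σ_ij C_ij],
with a CI from the F distribution: bounds 1 − (1 − α_c)·F⁻¹(a/2; df₁, df₂)
and the 1 − a/2 analogue, where F⁻¹ is the inverse survival function,
df₁ = retained rows − 1 and df₂ = df₁ × items. Qualitative bands: ≥ 0.95
redundant, ≥ 0.9 excellent, ≥ 0.8 acceptable. A zero total covariance leaves
alpha undefined and is reported as such.

The within-subject mean absolute deviation averages, over participants with
at least two scans, the mean |PAD − participant mean PAD|; the subject-level
random effect cancels inside the deviation, so the statistic isolates
scan-to-scan noise. Its CI is a percentile bootstrap over participants, and
modality-exclusion filters support reporting with and without the failure
modality.

## Numerical choices and degenerate inputs

- Truncated-normal calibration: `scipy.optimize.root` (hybr) on the first
  two truncated moments, solved in (μ, log σ); residuals above 1e−6 raise.
- All randomness flows from `numpy.random.SeedSequence` spawns of one master
  seed; identical (config, seed) reproduce cohorts and reports byte for
  byte, and the pipeline manifest records every stage seed.
- Least squares goes through statsmodels OLS/WLS; a level with zero age
  variance raises a singular-fit error rather than returning garbage.
- Slopes must be nonzero and finite for inversion; an exactly zero slope
  raises a correction error.
- Median of an even slice count is the midpoint of the two central values.
- Bootstrap replicates are generated in chunks (~2M cells) to bound memory.

## Problem sizes

Default study-shaped runs use 1540 participants (~5,900 scans). The test
suite and the acceptance script use 186-participant bias-estimation sets
(~841 scans, 200 replicates), 500-per-sample null simulations
(200 replicates), 250–400-participant pipelines, and bootstrap bases of a
few hundred replicates — sizes at which every Monte-Carlo check is stable
while the whole suite runs in about a minute.

## Limitations

- The generator's additive, linear, homoscedastic world is a deliberately
  simple stand-in; none of the package's guarantees about real predictors
  follow from passing tests on it.
- The mixed model's fixed-plus-random subject specification is kept for
  fidelity to the reporting convention it implements, not because it is
  statistically ideal; treat its intervals accordingly.
- χ² checks with very small splits (expected counts < 5) are approximate;
  the report carries raw statistics so users can substitute exact tests.
- WLS weighting and the unseen-level average are unweighted conventions;
  both are configuration points, not claims of optimality.
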