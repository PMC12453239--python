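# Methods

`fridisc` implements a dual-modality discrimination analysis for
fracture-related infection (FRI) versus matched uninfected controls from
plasma: a qualitative branch based on mid-infrared (FTIR) spectra of
dried plasma films and a quantitative branch based on TMT LC-MS/MS
protein abundance ratios, evaluated by a common bootstrap /
meta-analysis machinery and probed for cross-modal association.  This
note records the models, the defaults, the numerical choices, and the
limits of what the synthetic-data tests demonstrate.

## Study design assumed

A matched case-control cohort: n pairs (default 13), each pair one FRI
and one control sample matched on clinical covariates.  Every sample
contributes three replicate spectra (wells of a dried-film microplate)
and one row of a proteins × samples abundance-ratio table.  Plasma is
diluted 2:1 with potassium thiocyanate (KSCN) before drying, so each
spectrum carries an internal-standard band whose intensity is
independent of disease status.

## Spectral preprocessing

Per replicate spectrum, in this order:

1. **Area normalization** — divide by the trapezoidal area over the
   wavenumber grid, removing overall film-thickness variation.
2. **Additive log-ratio (ALR) to the internal standard** — subtract the
   log of the mean absorbance in the KSCN band (default 2000–2150 cm⁻¹,
   covering the thiocyanate C≡N stretch near 2060 cm⁻¹) from the log
   spectrum.  Absorbance is clipped at ε = 10⁻⁸ × row maximum before
   the logs because baseline regions of dried-film spectra can dip to
   or below zero.  The result is invariant to any positive rescaling of
   the spectrum.  The band *mean* (rather than peak height or area) is
   used as the reference because it is robust to grid density; the
   choice is configurable.
3. **Savitzky–Golay filtering** — local least-squares polynomial
   smoothing, default window 11 channels, order 3, derivative 0 —
   common FTIR smoothing practice; the window/order/derivative are
   exposed in `PreprocessConfig` and recorded in every results file.
   Edges use polynomial extrapolation of the terminal windows, so
   polynomials up to the filter order pass through exactly.
4. **Internal-standard excision** — channels inside the KSCN band are
   deleted so the standard cannot enter the classifier.
5. **Replicate averaging** — arithmetic mean of the three processed
   replicate spectra per sample.  Averaging *before* classification
   prevents replicate-level information from leaking across bootstrap
   splits (replicates of one sample can never straddle an
   in-bag/out-of-bag boundary).
6. **DCT compression** — the orthonormal DCT-II
   `X_k = sqrt(2/N) C_k Σ_n x_n cos(π/N (n+½)k)`, `C_0 = 1/√2`,
   `C_k = 1` otherwise.  Orthonormality (Parseval) is asserted to
   1e−10 in tests against an O(N²) evaluation of the definition.
7. **Frequency filtering** — coefficient k = 0 (the near-constant
   offset) is dropped, plus any coefficient whose across-sample
   variance is below 10⁻⁸ × the largest across-sample variance.
   Retained indices are recorded in the feature matrix.

## Univariate screening

Each retained feature is tested with a pooled-variance Student t-test
and Cohen's d (pooled-SD form); features with |d| > 0.5 survive.  The
rule is two-sided: a one-sided rule would silently discard
protective-direction features.  The pooled t (not Welch) matches the
pooled-SD denominator of d; both are configurable.  No multiplicity
correction is applied — the screen is a feature-selection device, not
an inference.

**Known optimism.**  The screen is fit once on the full dataset before
resampling, mirroring the printed order of the analysis it implements.
Because out-of-bag samples participated in selecting the features, the
downstream out-of-bag performance estimates are optimistic.  This is
not a small effect: on no-effect synthetic data at the default scale
(13+13 pairs, ~860 DCT coefficients, |d| > 0.5 keeping ~200), the
pooled out-of-bag AUROC sits near 0.85 rather than 0.5.  The
acceptance suite measures this directly (the null-calibration check
fails, and is reported failing, under this design), and every results
record carries `filter_fit_on_full_data: true`.  Users wanting honest
generalization estimates must nest the screen inside the resampling;
the package keeps the printed order because reproducing that pipeline
is its purpose.

## Classification

Elastic-net penalized logistic regression, minimizing

    L(β) = (1/N) Σ_i [−y_i log p_i − (1−y_i) log(1−p_i)]
           + λ (α‖β‖₁ + ((1−α)/2)‖β‖₂²),   p_i = σ(β₀ + x_iᵀβ)

by cyclic coordinate descent on the IRLS quadratic approximation
(glmnet-style), intercept unpenalized, features standardized inside the
fit.  α defaults to 0.5 (an even ℓ1/ℓ2 mix, exposed in `FitConfig` and
recorded in results).  Each IRLS step is safeguarded by halving toward
the previous iterate whenever the exact objective would rise, making
the objective trajectory non-increasing by construction; convergence is
declared at a max coefficient change below 1e−7 (tight, so that oracle
comparisons at 1e−4 are meaningful).  Weights p(1−p) are floored at
1e−5 for numerical stability.

The **50-coefficient cap** is enforced through the regularization path:
λ values are log-spaced (25 points, 3 decades) from the smallest
all-zero λ downward, the path stops before the nonzero count would
exceed the cap, and among admissible path points the one with the best
training deviance is kept.  Correctness of the solver is checked
against an independent projected-gradient minimizer of the same
objective (β split into positive/negative parts) on random instances,
and against the lasso/ridge special cases α = 1 and α = 0.

## Bootstrap sessions and fixed-effect pooling

The resampling unit is the **matched pair**, preserving the paired
design: one session draws 13 pairs with replacement B = 100 times (50
in the scaled acceptance runs), trains on the in-bag samples and
evaluates AUROC (Mann–Whitney estimator), sensitivity and specificity
(probability threshold 0.5) on the out-of-bag pairs.  Pair-level
resampling guarantees every non-empty out-of-bag set contains both
classes; the rare all-pairs-drawn resample is redrawn and counted.
S = 100 sessions (10 scaled) differing only in their recorded seeds are
pooled by a fixed-effect inverse-variance meta-analysis: session weight
1/v with v = (variance of the B per-resample metrics)/B, pooled CI95 =
estimate ± 1.96/√Σ(1/v), clipped to [0, 1].  Unweighted pooling is
available (`pooling="mean"`).

Because all sessions see the same dataset, the pooled CI reflects only
seed noise, not sampling uncertainty — it quantifies the Monte-Carlo
stability of the estimate, and at these B and S it is very narrow
(halfwidth ~0.02).  It must not be read as a confidence interval for
generalization performance on new cohorts.

Feature importance is the fraction of all resamples (across sessions)
in which a feature received a nonzero coefficient; the top-40 list uses
this frequency with ties broken lexicographically for determinism.

## MS branch

Protein abundance ratios are natural-log transformed (they are
multiplicative quantities) and fed to exactly the same screening /
bootstrap / pooling code path; the spectral stages (smoothing, DCT,
frequency filter) are skipped because protein columns do not form a
continuous correlated sequence.

## Cross-modal association

CCA between the most discriminatory raw-wavenumber channels and the
most discriminatory proteins (top 8 per modality by |d|; 8 ≲ n/3 keeps
the within-set covariances well conditioned at n = 26).  Canonical
correlations come from the SVD of `Σ_xx^{-1/2} Σ_xy Σ_yy^{-1/2}` with
eigenvalue-floor ridge stabilization (recorded) when a covariance is
near-singular.  Significance: rows of Y permuted (default 1000 times),
`p = (1 + #{ρ_perm ≥ ρ_obs})/(1 + n_perm)` — valid and conservative.

The cross-modal autoencoder passes each modality through three dense
tanh layers (64, 16, 4) to a 2-node bottleneck; the mirrored decoder
reconstructs the *opposite* modality, and the summed cross-
reconstruction MSE is minimized with full-batch Adam (lr 0.01, 500
epochs), all in numpy.  The 2-D embedding (mean of the two bottleneck
codes) is scored for class separation by the in-sample AUROC of a
Fisher discriminant; train/validation splitting is deliberately absent
(n = 26; the tool is exploratory and its output is a report, not a
model).

## Cohort statistics

2×2 categorical cohort variables are tested with a two-sided Fisher
exact test: hypergeometric enumeration, summing all tables (same
margins) whose point probability is ≤ the observed one with a 1e−7
relative tie slack — the convention of R's `fisher.test`, which
reproduces the published cohort table's printed p-values from its
printed counts (those counts ship as a packaged CSV).  Continuous
cohort variables use the two-sided matched (paired) t-test; the
published table's continuous rows cannot be re-tested because only
summary statistics, not pair-level values, were published.

## Synthetic data generator

Spectra: six Gaussian bands at plasma-like positions (amide I 1650,
amide II 1545, CH stretch 2925, sugar/phosphate 1080, COO⁻/CH 1400,
amide A 3300 cm⁻¹) with log-normal sample-level amplitudes (CV
0.15–0.20), a KSCN band (2060 cm⁻¹, CV 0.08) independent of class, a
random quadratic baseline per replicate (amplitude 0.02), replicate
gain jitter (CV 0.03) and i.i.d. channel noise (SD 0.003), on a
901-channel 400–4000 cm⁻¹ grid (4 cm⁻¹ spacing).  The class effect
adds `effect_size × between-sample SD` to the FRI mean amplitude of
the affected bands (default: the three strongest), so the planted
standardized effect equals `effect_size` by construction; a Monte-Carlo
test confirms the empirical Cohen's d is within ±0.15 of the target.
Band positions and widths are plausible rather than fitted to any real
spectrum; no published per-band effect sizes exist to calibrate
against.

Proteins: 1000 log-normal ratio columns (CV 0.30); 32 columns — chosen
deterministically so truth sets are seed-invariant — get a 0.8-SD
log-mean shift in FRI samples, emulating the scale of differential
abundance reported for this disease contrast in prior proteomic work.

The generator does **not** simulate instrument interferograms,
water-vapor lines, atmospheric compensation artifacts, scatter
(EMSC-type) effects, batch structure, TMT channel-level noise, missing
proteins, or any correlation between the two modalities beyond the
shared class label.  Passing tests therefore demonstrate correctness
of the statistical machinery under idealized conditions, not
performance on real spectra; in particular the planted-effect AUROC is
a qualitative analogue of — not a reproduction of — any published
performance figure, since the underlying cohort data are not public.

## Problem sizes used in checks

Acceptance-level simulations use 20 datasets per condition with 10
sessions × 50 resamples at the full 13-pair, 901-channel,
1000-protein geometry; unit tests use a 241-channel grid and smaller
session counts.  Permutation checks use 200 datasets × 200
permutations.  These sizes give Monte-Carlo error comfortably below
every asserted margin.

## Degenerate inputs and tie-breaks

Zero-pooled-variance features are dropped from screening with a
warning; an all-constant feature reaching the solver raises.  A session
whose B metric values are all identical has zero variance and cannot be
inverse-variance pooled; this raises rather than silently reweighting.
Resamples with an empty out-of-bag set are redrawn (bounded, counted).
AUROC ties count ½.  Feature-frequency ties rank lexicographically.
CCA correlations are clipped to [0, 1] against rounding above 1.
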