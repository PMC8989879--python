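# Methods

## Model and procedure

The pipeline estimates, from baseline data alone, where an individual sits
on a trajectory from clinically stable ageing towards Alzheimer's-type
decline, and uses that position to predict future regional tau
accumulation.

**Classifier.** Two-class GMLVQ with one prototype per class and a full
metric tensor Λ = ΩᵀΩ.  Features are z-scored on the training split
(the APOE4 indicator included; a learned full metric could absorb raw
scales, but standardization keeps the fixed learning rates well behaved).
Squared distances are d_Λ(x, w) = (x − w)ᵀΛ(x − w); the GLVQ cost sums
φ(μ) over samples with μ = (d_J − d_K)/(d_J + d_K) ∈ [−1, 1], d_J the
distance to the own-class prototype.  Assumptions: two labelled classes
with at least two members each; no missing features; classes
representable by single prototypes (multi-prototype and localized-metric
variants are out of scope).

**Prognostic index.** Samples and prototypes are mapped through the
symmetric PSD square root Λ^½ (eigendecomposition, negative eigenvalues
clipped at 0) and the index is the projection onto the prototype axis
normalized by its squared length, so the Stable prototype maps to exactly
0 and the Declining prototype to exactly 1.  Values outside [0, 1] are
legal and meaningful (beyond-prototype severity).  Components orthogonal
to the axis in metric space do not move the index.

**Threshold.** A multinomial logistic regression of the three-class
longitudinal diagnosis (Stable / Declining / Alzheimer's Clinical
Syndrome) on the index, Stable as reference; the stratification boundary
is the s where P(Stable | s) = 0.5, located by bisection to 1e-8.
Stratification uses strict inequality: a subject is Declining iff
s > threshold.  An ordinal logistic model would also be defensible; the
multinomial form is implemented because it makes no ordering assumption
and its Stable-class probability is the only quantity used.  Under
complete separation the maximum-likelihood fit degenerates, so the
threshold falls back to the midpoint of the empirical gap and is flagged.

**Cross-validation.** Class-balanced random resampling: each of the (by
default 400) resamples draws floor(n_minority/2) subjects per class as a
balanced training set (floor handles odd counts), tests on the remainder,
and accumulates sensitivity (Declining as the positive class) and
specificity; balanced accuracy is the mean of (TPR + TNR)/2 over
resamples.

**Rates.** Annualized rate = two-point difference over the interval, or
the OLS slope (with intercept) for three or more observations; the two
rules coincide at n = 2.  Times are years from baseline; calendar
handling is the caller's concern.  PACC uses the identical estimator.

**Group inference.** Per-ROI one-sample right-tailed t against 0,
*uncorrected* at α = 0.05 by design (an FDR option exists but is off by
default, matching the analysis this package implements).  The "global"
contrast treats the 36 per-ROI group means as observations in a pooled
two-sample t (df = 70 for 36 ROIs); a subject-level alternative is
available behind a flag but is not the default because the ROI-mean
formulation is what the df pattern of the original analysis implies.
Regional specificity uses the one-way random-effects single-measure ICC
for k = 2 raters, F = MSB/MSW with df (n − 1, n), CI from F quantiles —
the single-measure one-way variant is the only one consistent with that
df pattern, and two-way variants are deliberately not implemented.
Agreement with baseline syndromic diagnosis uses Cohen's kappa with the
Fleiss-style asymptotic SE for the CI and the null-variance z-test for p.
Note: applying the standard kappa formula to the published 2×2
stratification-vs-diagnosis table (40/32; 19/24) gives κ ≈ 0.107, not the
0.09 printed alongside it; this package reports the standard formula and
records the discrepancy rather than reverse-engineering a variant.

**Trial power.** One-sample normal-approximation size per arm,
n = ⌈((z₁₋α∕₂ + z_power)·σ/(r·|μ|))²⌉, defaults r = 0.25, α = 0.05
(two-sided), power 0.8 — a hypothetical arm whose mean rate is compared
against the untreated mean.  One-sided and noncentral-t variants are
exposed.  μ = 0 yields an explicitly infinite n rather than an error.
Percentage reductions between stratification schemes are computed on the
pre-ceiling real-valued n (the ceiling is applied last) to avoid 1-unit
rounding artifacts.

**Regression transfer.** For ROIs passing the regional accumulation test,
rate = β·s + β₀ is fitted by IRLS with Tukey-bisquare weights (c = 4.685)
and MAD scale, converging on coefficients at 1e-8 or 50 iterations; on
clean data this equals OLS exactly.  Only ROIs whose slope is significant
(p < 0.05, uncorrected) are transferred.  Prediction accuracy is robust
shared variance: 100·r² of the percentage-bend correlation (bend 0.2);
a skipped-correlation option is provided, percentage-bend is the default
because it is the simplest well-studied robust estimator and the choice
in the original toolbox chain is not pinned down.

## Synthetic cohorts

The generator exists because the cohorts this method targets are
access-restricted; its defaults are declared test fixtures that emulate
the *structure* and *effect regimes* of such data, not estimates of any
real cohort.

A latent progression score θ drives everything: per-class Normal draws
(Stable N(0, 0.2²), Declining N(1, 0.35²), ACS N(1.8, 0.4²)) chosen so the
classes are well but not perfectly separated (balanced CV accuracy ≈ 0.9,
the regime of the published classifier).  Baseline features are linear
Gaussian readouts:

| quantity | law | default | why |
|---|---|---|---|
| amyloid (CL) | a₀ + a₁θ + ε | a₀=10, a₁=55, sd 15, clipped to [−30, 220] | bimodal across classes; Stable centres near the 22.5 CL positivity point's negative side, Declining well above it |
| GM density | g₀ − g₁θ + ε | g₀=0.60, g₁=0.15, sd 0.05 | declining medial-temporal density with overlap |
| APOE4 | Bernoulli(logistic(−1 + 1.5θ)) | — | carrier prevalence ≈ 27% (Stable) to ≈ 62% (Declining) |
| baseline dx | MCI w.p. logistic(−0.85 + 0.3θ) | — | weak link ⇒ near-chance agreement with the biomarker stratification |

Longitudinal tau per ROI r: true rate = b₀ᵣ + b₁ᵣθ + N(0, 0.02) SUVR/yr,
with b₁ = 0.03 only in the seven early-vulnerable temporal/parietal ROIs
(fusiform, inferior temporal, supramarginal, inferior/superior parietal,
precuneus, banks of the STS) and b₁ = 0 elsewhere; every ROI shares
b₀ = −0.003 SUVR/yr, a small negative drift standing for reference-region
and tracer-washout effects in non-accumulating tissue.  Observed SUVR at
scan time t adds N(0, 0.01) measurement noise to baseline(θ) + rate·t over
2–4 scans spaced 1.2 ± 0.4 yr (intervals floored at 0.3 yr).  PACC rate is
−0.5θ + N(0, 0.3) points/yr with 0.5-point measurement noise.  The noise
levels were set so the Declining stratum's index-vs-rate shared variance
lands in the ~15–30% band and the Stable stratum near the null level, the
contrast the transfer analysis is about.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: non-linear or thresholded θ→rate links
(floor effects in truly stable individuals), site/scanner batch effects,
missing visits correlated with decline, APOE allele dosage, measurement
error in the grey-matter score, and any image-level artefact.  Tests
against it validate the *estimators and pipeline logic*, not clinical
performance.

## Numerical choices

- Training: batch gradient descent, rates 0.05 (prototypes) / 0.005 (Ω)
  with 1/(1 + epoch/100) decay, ≤500 epochs, stop at relative cost change
  < 1e-7.  Steps that would increase the cost are rejected and retried at
  half step (the backtracking factor persists), so accepted steps are
  non-increasing in cost.  Ω is renormalized after every epoch so
  trace(Λ) = 1; μ is invariant to that rescaling, so renormalization never
  changes the cost.
- Prototype init at class-conditional means of standardized features
  (a median-init flag exists); Ω₀ = I/√d.  Mean init is the default for
  differentiability of the whole construction; coincident class centres
  are jittered deterministically from the seed.
- φ = identity by default (standard GLVQ); a sigmoid link is available.
- Λ^½ by `eigh` with eigenvalues clipped at 0; asymmetry beyond 1e-9
  rejected.
- Degenerate GLVQ sample (zero distance to both prototypes): μ defined
  as 0 with zero gradient.
- Amyloid positivity boundary is inclusive (≥ 22.5 CL); SUVR thresholds
  are always converted to centiloids before comparison because only the
  1.11 SUVR value is consistent with the printed conversion at 22.5 CL.
- All CSV output at 12 significant digits; manifests record SHA-256 of
  every stage output plus the global seed, and a fixed seed reproduces
  every file bit-identically.

## Problem sizes

Default study conditions are 250 subjects per class with 36 ROIs and 2–4
scans per subject; the cross-validation uses 400 resamples.  These sizes
keep a full three-cohort pipeline run under a minute on one CPU while
leaving the qualitative contrasts (regional specificity, stratified power
gains, transfer asymmetry) statistically stable.

## Limitations

- Single-prototype, global-metric GMLVQ only; no kernelized variants.
- The probabilistic threshold assumes a monotone decreasing Stable-class
  probability in s; wildly non-monotone score distributions would need an
  ordinal or nonparametric boundary instead.
- The power formula is the normal approximation; for very small n the
  noncentral-t option should be preferred.
- Robust-regression inference relies on asymptotic RLM standard errors;
  its intervals undercover slightly below n ≈ 50.
- Rates are per-subject least squares, not mixed-effects shrinkage
  estimates; with two scans the rate estimate is noise-dominated when the
  scan interval is short.
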