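# tautraj

A trajectory-modelling pipeline for early Alzheimer's disease: it learns a
**prognostic index** from three baseline measures — cortical amyloid burden
(centiloids), a medial-temporal grey-matter density score, and APOE ε4
carrier status — and uses that index to predict **future regional tau
accumulation**, stratify cohorts for clinical trials, and transfer
individualised rate predictions across cohorts.  It is written for
biostatisticians and imaging researchers who work with longitudinal
tau-PET (SUVR) and cognitive (PACC) endpoints.

## The model

The classifier is Generalised Matrix Learning Vector Quantisation (GMLVQ):
one prototype **w**ₖ per class (Clinically Stable, Clinically Declining) and
a full trainable metric tensor Λ = ΩᵀΩ (symmetric PSD, unit trace), with
distances

d_Λ(**x**, **w**) = (**x** − **w**)ᵀ Λ (**x** − **w**).

Training minimises the GLVQ cost Σᵢ φ(μᵢ), μᵢ = (d_J − d_K)/(d_J + d_K),
by batch gradient descent on the prototypes and Ω with analytic gradients.

The prognostic index is the **scalar projection** onto the prototype axis
in the learnt space.  With **X** = Λ^½ **x** and **W**ₛ, **W**_d the
transformed Stable/Declining prototypes,

s = ⟨**X** − **W**ₛ, **W**_d − **W**ₛ⟩ / ‖**W**_d − **W**ₛ‖²,

so s = 0 at the Stable prototype and s = 1 at the Declining prototype.  A
three-class logistic model of diagnosis on s locates the boundary where an
individual becomes less than 50% likely to be Clinically Stable; subjects
above it are stratified as Clinically Declining.

Downstream stages: annualized rates of change from longitudinal series
(two-point difference, or the OLS slope for ≥3 scans); per-ROI one-sided
t-tests of accumulation; across-ROI group contrasts, one-way ICC and
Cohen's kappa; per-arm trial sample sizes n = ⌈((z₁₋α∕₂ + z_pow)·σ/(r·|μ|))²⌉
for detecting a fractional rate reduction r; and per-ROI robust (bisquare)
regressions of rate on s, transferred to an independent cohort and scored
by percentage-bend shared variance.

Because the cohorts the method was developed on are access-restricted, the
package ships a seeded synthetic-cohort generator with the statistical
structure the analysis assumes (a latent progression score driving all
biomarkers); every stage is tested against it.  See `docs/methods.md`.

## Worked example

```python
import pandas as pd
from tautraj import (GMLVQ, SyntheticConfig, generate_cohort,
                     balanced_resampling_cv, fit_threshold, stratify,
                     build_rate_table, regional_accumulation_tests)

train = generate_cohort(SyntheticConfig(seed=0))          # 250/class
model = GMLVQ.from_dataframe(train.cohort_table).fit(seed=0)
print(model.summary())
```

```
GMLVQ Results
============================================================
classes: ClinicallyStable vs ClinicallyDeclining
epochs run: 160  converged: True  final cost: -378.917

prototypes (standardized units):
  class                  amyloid_centiloid mtl_gm_density          apoe4
  ClinicallyStable              -0.8465         0.7510        -0.8385
  ClinicallyDeclining            0.7940        -0.7209         0.6677

metric tensor Lambda (unit trace; diagonal = feature relevances):
  amyloid_centiloid              0.8242        -0.3621         0.1175
  mtl_gm_density                -0.3621         0.1591        -0.0516
  apoe4                          0.1175        -0.0516         0.0168
```

The prototypes sit where the classes live (high amyloid, low grey-matter
density and more ε4 carriers for the Declining class), and the metric
concentrates most of its unit trace on amyloid.  Continuing:

```python
feats = ["amyloid_centiloid", "mtl_gm_density", "apoe4"]
s = model.scalar_projection(train.cohort_table[feats].to_numpy())
thr = fit_threshold(s, train.cohort_table.class_label).threshold_s
print(f"probabilistic threshold on the index: s = {thr:.3f}")

cv = balanced_resampling_cv(train.cohort_table, n_resamples=400, seed=0)
print(cv.summary())

test = generate_cohort(SyntheticConfig(seed=1))
s_test = pd.Series(model.scalar_projection(test.cohort_table[feats].to_numpy()),
                   index=test.cohort_table.subject_id)
strata = stratify(s_test.to_numpy(), thr)
rates = build_rate_table(test.series)
declining = s_test.index[strata == "ClinicallyDeclining"]
res = regional_accumulation_tests(rates, declining)
print("ROIs accumulating tau in the Declining stratum:",
      ", ".join(sorted(res.loc[res.significant, "roi"])))
```

```
probabilistic threshold on the index: s = 0.470
Balanced resampling CV (400 resamples)
  balanced accuracy: 0.932
  sensitivity (ClinicallyDeclining): 0.916
  specificity: 0.947
ROIs accumulating tau in the Declining stratum: bankssts, fusiform,
inferiorparietal, inferiortemporal, precuneus, superiorparietal, supramarginal
```

The classifier separates the two trajectory classes with ~93% balanced
cross-validated accuracy, the boundary on the index falls near s ≈ 0.5,
and the Declining stratum of a held-out cohort shows significant tau
accumulation in exactly the temporal/parietal regions the generator makes
vulnerable — the Stable stratum shows none.

The same analyses are available from the shell:

```sh
tautraj run --out results/full --seed 0          # full pipeline + manifest
tautraj simulate --out sim --seed 0              # individual stages
tautraj train --cohort sim/cohort.csv --out model.yaml
```

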