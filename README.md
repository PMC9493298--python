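# pet-hetero

Quantification of **intratumor metabolic heterogeneity** from ¹⁸F-FDG PET
SUV volumes, with the downstream recurrence analysis used in prognostic
imaging studies — plus fully synthetic digital phantoms and patient cohorts
so every stage can be verified against closed-form ground truth on a laptop.

The package is aimed at imaging scientists and biostatisticians who want a
reproducible, testable implementation of threshold-based PET tumor
quantification and its survival analysis, without access to patient data.

## What it computes

From a 3-D SUV volume and a tumor bounding box, the nine per-patient
parameters standard in this literature:

- **SUVmax** — maximum standardized uptake value in the tumor VOI.
- **MTV₂.₅ / MTV₄₀%** — metabolic tumor volume (mL): the volume of the
  26-connected superlevel set {SUV ≥ t} containing the hottest voxel, with
  t = 2.5 (fixed) or t = 0.40·SUVmax (relative).
- **TLG₂.₅ / TLG₄₀%** — total lesion glycolysis (g): MTV × SUVmean.
- **CV₂.₅ / CV₄₀%** — coefficient of variation σ(SUV)/SUVmean inside each
  VOI; a first-order heterogeneity measure.
- **HI-1** — heterogeneity index by the fixed-threshold method: the negated
  ordinary-least-squares slope of MTV(t) over t ∈ {2.5, 3.0, 3.5} SUV
  (mL per SUV unit). Steeper MTV decay ⇒ more heterogeneous uptake.
- **HI-2** — heterogeneity index by the percentage-threshold method: the
  negated OLS slope of MTV over thresholds 30%–70% of SUVmax in 10-point
  steps (mL per percentage point).

Around this core:

- `phantom` — spherical digital phantoms (uniform, linear-decay,
  necrotic-core profiles) with *closed-form* MTV(t), HI-1 and HI-2, plus
  optional Gaussian PSF blur and noise to emulate partial-volume effects.
- `cohort_sim` — synthetic patient cohorts: binary pathology covariates at
  given prevalences, a log-normal HI-1 marginal matched to a printed
  median/IQR, and disease-free survival generated under proportional
  hazards with a baseline hazard calibrated to a target event fraction.
- `survival_stats` — Shapiro–Wilk-routed group comparisons
  (χ² / t / rank-sum), Kaplan–Meier, log-rank, univariate and multivariate
  Cox regression (Efron ties, via lifelines), and ROC/Youden optimal
  cutoffs.
- `pipeline` / `pet-hetero` CLI — one-command, one-seed orchestration of
  phantom → metrics → cohort → survival report with a reproducibility
  manifest.

## Worked example

A linear-decay sphere SUV(r) = 10·(1 − r/20 mm) on a 0.5 mm grid has
analytic MTVs of 14.137/11.494/9.203 mL at thresholds 2.5/3.0/3.5, hence an
analytic HI-1 of 4.934 mL per SUV unit:

```python
from pet_hetero import (PhantomSpec, make_phantom, BoundingBox,
                        compute_all_parameters, analytic_hi)

spec = PhantomSpec(radius_mm=20.0, profile="linear_decay", s_peak=10.0,
                   background_suv=0.5, spacing_mm=(0.5, 0.5, 0.5),
                   extent_mm=(44.5, 44.5, 44.5))
volume = make_phantom(spec)
params = compute_all_parameters(volume, BoundingBox.whole(volume))
for k, v in params.as_row().items():
    print(f"{k:>10s}  {v:8.3f}")
print("analytic HI-1:", round(analytic_hi(spec, [2.5, 3.0, 3.5]), 3))
```

prints

```
   suv_max    10.000
mtv_2_5_ml    14.135
 mtv_40_ml     7.222
 tlg_2_5_g    61.845
  tlg_40_g    39.746
    cv_2_5     0.332
     cv_40     0.211
      hi_1     4.944
      hi_2     0.263
analytic HI-1: 4.934
```

The voxelized MTV₂.₅ (14.135 mL) and HI-1 (4.944) sit within discretization
error of the closed forms; CV > 0 and HI > 0 reflect the radially decaying
(heterogeneous) uptake, and both would be exactly 0 for a uniform sphere.

The same pipeline from a shell:

```sh
pet-hetero pipeline --seed 7 --out demo_run/
```

writes `phantom_parameters.csv`, `cohort.csv`, the comparison/Cox/cutoff
tables, Kaplan–Meier curve points, and `manifest.json` into `demo_run/`.

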