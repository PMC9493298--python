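# Methods

## Tumor segmentation and the VOI

Manual VOI placement is operationalized as a deterministic rule: the user
supplies a voxel-index bounding box around the lesion; inside it the closed
superlevel set {SUV ≥ t} is formed and reduced to the connected component
that contains the box's maximum-SUV voxel. Connectivity is 26-neighborhood
by default (6-neighborhood available via the `connectivity` argument), the
standard choice for PET lesion growing. Ties at exactly t are included
(`≥`), which makes a perfectly uniform tumor an exact fixed point of the
heterogeneity measures rather than an approximate one. Fixed thresholds use
absolute SUV; relative thresholds resolve f·SUVmax against the maximum
*inside the box*. A threshold no voxel reaches raises `EmptyVoiError` — a
relative threshold with f ≤ 1 can never do so on positive uptake.

Input volumes are assumed to be already SUV-scaled; conversion from raw
activity (decay correction, dose/weight normalization) and any DICOM
handling are out of scope. NIfTI-1 is the on-disk format, with spacing
taken from the header zooms.

## The nine parameters

MTV is voxel count × voxel volume (mm³ → mL). TLG = MTV × SUVmean (g,
SUV read as g/mL-normalized). CV = sample SD / mean of SUV inside the VOI;
the SD uses the n−1 denominator (conventional for CV reporting; the
difference is negligible at realistic VOI sizes), with SD ≡ 0 for a
single-voxel VOI.

The heterogeneity indices regress MTV on a ladder of thresholds and negate
the OLS slope, so a faster collapse of tumor volume with rising threshold —
the signature of spatially heterogeneous uptake — gives a larger index:

- **HI-1**: fixed thresholds {2.5, 3.0, 3.5} SUV; units mL per SUV unit.
- **HI-2**: relative thresholds {30, 40, 50, 60, 70}% of SUVmax, with the
  regression abscissa in percentage points; units mL per percentage point.
  Only the 30–70% range is conventionally fixed; the five-step/10-point
  grid and the percentage-point abscissa are this package's documented
  convention, chosen to keep HI-2 magnitudes in the customary ~0.3–0.8
  range (a fraction-scale abscissa would multiply them by 100).

The slope is computed from centered normal equations rather than a generic
polynomial fit so that a flat MTV curve yields exactly 0.0, making the
uniform-tumor fixed point (CV = HI-1 = HI-2 = 0) exact, not approximate.
Tumors whose SUVmax does not clear a fixed ladder (≤ 3.5) get NaN for the
affected parameters plus a machine-parsable `MISSING_PARAMETER` log line;
the regression is never truncated to fewer points, and missing values are
never silently zeroed. A cohort meeting the usual inclusion criterion
(tumor uptake above background, SUVmax well above 3.5) never triggers this.

Scale behavior worth knowing: CV₄₀% and HI-2 are invariant to rescaling all
SUVs by k > 0 (relative thresholds); CV₂.₅ and HI-1 are not, because the
absolute threshold then cuts a different isocontour. The tests pin all
three behaviors.

## Phantoms and their oracles

Only spherical phantoms with radial profiles are generated, because every
oracle then stays closed-form: for the linear-decay profile
SUV(r) = s_peak·(1 − r/R), the superlevel radius at threshold t is
R·(1 − t/s_peak), so MTV(t) = (4/3)π R³(1 − t/s_peak)³; uniform spheres
give a constant MTV; necrotic cores give a shell volume. `analytic_hi`
applies the same OLS convention to these closed forms. Voxels are sampled
at their centers without supersampling; the discretization error of a
voxel-count MTV is about one voxel shell, shrinking linearly with spacing
(tested by grid refinement). On a 0.5 mm grid the reference linear-decay
phantom reproduces its analytic MTVs within 2% and HI-1 within 5%. Test
fixtures use an odd number of voxels per axis so a voxel center coincides
with the sphere center and the measured SUVmax equals the profile peak.

Gaussian PSF blur (stated FWHM, applied in mm space) plus additive
zero-clipped Gaussian noise is the simplest model exhibiting partial-volume
phenomenology: blur strictly shrinks high-threshold MTVs of a sharp sphere
and makes the measured CV of a homogeneous tumor positive — the direction
real scanners push heterogeneity estimates. No Poisson statistics,
attenuation, scatter or reconstruction modeling is attempted, so passing
tests certify the *measurement pipeline*, not scanner realism.

## Cohort generator

Each patient carries three independent Bernoulli pathology covariates
(regional lymph node metastasis, prevalence 0.521; nerve invasion, 0.257;
tumor thrombus, 0.314) and a continuous HI-1 drawn log-normal. Only the
marginals are known from published tables, so covariates are drawn
independently — a documented limitation; real pathology covariates
correlate. The log-normal is fitted by quantile matching on the log scale:
μ = ln(median), σ = (ln q3 − ln q1)/(2·z₀.₇₅); for median 12.26 and IQR
7.54–19.36 this gives μ ≈ 2.506, σ ≈ 0.699.

Disease-free survival is inverse-transform sampled from an exponential
baseline hazard under proportional hazards: T = −ln U / (λ₀·exp(x'β)),
with default β = ln of the generative hazard ratios (2.95, 1.68, 2.37,
1.02 per HI-1 unit). The exponential baseline is the simplest PH-compatible
choice; calibration makes its scale irrelevant to hazard-ratio recovery.
Censoring is administrative: follow-up is drawn from a two-piece uniform on
[min, median] ∪ [median, max] months (default 1/34/87) — the only three
order statistics typically printed. Recurrence and death are not
distinguished; both are DFS events.

λ₀ is calibrated by bisection (geometric midpoints, since the hazard lives
on a log scale) so the expected event fraction hits the target (default
0.257, tolerance ±0.005). One large calibration sample of exp(x'β), one
set of exponential deviates and one set of censoring times are drawn with a
fixed internal seed and reused across bisection steps, making the objective
monotone and the result deterministic and independent of the cohort seed.
The calibration population is always the distribution the hazard will
actually see: the log-normal marginal for tabular cohorts, and the
phantom-derived index distribution for imaging cohorts.

`generate_imaging_cohort` closes the loop: each patient gets a linear-decay
phantom with uniformly drawn radius (10–24 mm) and peak uptake (6–15 SUV);
the *analytic* HI-1 drives the hazard while the *measured* HI-1 (computed
by the metrics pipeline from the rasterized volume) enters the analysis
table, so measurement error attenuates estimates exactly as it would in a
real study. The default 1.5 mm voxel grid keeps the measured-vs-analytic
HI-1 correlation above 0.99 on noise-free phantoms; at 2 mm discretization
error of the smallest tumors pulls it to ≈0.986.

## Survival analysis

Group comparisons route by distribution: binary variables get the classical
uncorrected χ² on the contingency table (matching the hand formula and the
convention of the tables this mirrors; Yates correction would roughly
double small-table p-values), continuous variables get Student's t-test
when both groups pass Shapiro–Wilk at α = 0.05 and the Wilcoxon rank-sum
test otherwise. Kaplan–Meier, the Mantel–Haenszel log-rank test and Cox
regression are delegated to lifelines behind the package's own result
types; Cox ties are handled by Efron's method (lifelines' only method — a
Breslow toggle is deliberately not offered), with Wald 95% CIs and
p-values. Constant covariates and event-free inputs raise typed errors
instead of returning degenerate fits. Multivariate model composition
follows the usual screening rule: covariates significant in univariate
analysis enter the multivariate model. No multiple-testing correction is
applied, matching the practice of the studies this pipeline mirrors.

The ROC cutoff maximizes the Youden index J = sensitivity + specificity − 1
over midpoints between adjacent distinct marker values, ties broken toward
the smaller cutoff; higher marker values are taken to predict the event;
AUC is trapezoidal and therefore identical to the normalized Mann–Whitney
U. A maximally-selected log-rank criterion was considered and not adopted
as default: the Youden rule on the event indicator is the literal ROC
construction, is deterministic, and needs no resampling correction.

## Problem sizes and verification

The package's own checks use: 0.5 mm grids (≈ 90³ voxels) for oracle
agreement; 100 randomized 2 mm phantoms for threshold monotonicity; a
6-patient fixture whose Cox coefficient is compared with brute-force
maximization of the written-out partial likelihood (1e−4 agreement);
10,000-patient cohorts for hazard-ratio recovery (each generative HR
recovered within 10% or its own 95% CI, the per-unit HI-1 HR within 1%);
and 200 replicates of n = 500 under a fully null model, where per-covariate
Wald rejection at α = 0.05 must stay within [0.03, 0.07]. All tolerances
are Monte-Carlo bands around the generator's own truth — the synthetic
cohort shows that the pipeline *recovers what it simulates*; it cannot
certify agreement with any particular patient population.

## Known limitations

- Spheres with radial profiles only; no ellipsoids, lobulated shapes or
  multifocal lesions (the VOI keeps a single connected component).
- No partial-volume correction, by design; blur is modeled but never
  corrected for.
- Independent covariates and a single censoring mechanism; no competing
  risks, no time-varying effects.
- The per-unit HI-1 hazard ratio entangles scale with the index's unit
  convention (mL per SUV unit here); a different HI-2 abscissa convention
  would rescale that coefficient accordingly.
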