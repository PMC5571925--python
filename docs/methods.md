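# Methods

This note documents the models and procedures implemented in `petsarc`, the
assumptions behind them, the defaults and why they were chosen, and what the
synthetic-data generators do and do not emulate.

## Image model and conventions

Volumes are axis-aligned 3-D grids of body-weight SUV (g/mL) with anisotropic
voxel spacing in mm. Array indices map to physical coordinates by
`index × spacing`; orientation and origin metadata beyond spacing are not
interpreted, which restricts the package to axis-aligned NIfTI input (a
documented limitation — DICOM ingestion and resampling are the user's
responsibility). Masks are binary grids aligned voxel-for-voxel with their
companion volume.

## Phantom generator

A phantom is an ellipsoidal lesion on a noisy low-uptake background. Lesion
membership uses the voxel-center test (a voxel belongs iff its center lies
inside the ellipsoid); no partial-volume weighting is applied, so the mask
semantics match those used by every downstream feature. Noise is additive
Gaussian, clipped at zero, because SUV images are non-negative; realistic
scanner point-spread, scatter and reconstruction artifacts are out of scope.
`lesion_suv` is the pre-noise peak; texture patterns (`uniform`, a linear
`gradient`, a two-level `checkerboard` whose matrices are hand-computable,
and Gaussian `blobs`) modulate downward from it.

Paired studies model chemotherapy response: the post-therapy lesion has its
uptake multiplied by `uptake_scale` — floored at the background level, so a
scale of 0 makes the lesion vanish into the background — and its semi-axes
scaled by `volume_scale^(1/3)`. The floor is what lets a complete metabolic
response be both physically sensible (tissue does not become colder than
background) and exactly detectable downstream.

Every generator draws from `numpy.random.default_rng(seed)`; a fixed seed
gives bit-identical output, which the tests rely on.

## Segmentation

The VOI is delineated by iterative adaptive thresholding:

    T_0     = t0_fraction × SUVmax(3×3×3 region around the seed)
    T_{k+1} = α · mean(SUV inside region_k) + β · background

where `region_k` is the connected component above `T_k` containing the seed.
Defaults: α = 0.5, β = 1.0, `t0_fraction` = 0.4, relative tolerance 0.01,
100-iteration cap, 26-connectivity — i.e. the converged threshold is half the
lesion mean plus the background, a member of the family of contrast-adaptive
thresholds used for PET tumors. The background estimate is a caller-supplied
scalar rather than auto-detected, to avoid hiding an unspecified step. On
noise-free two-level phantoms the region stabilizes after one update and the
threshold sequence converges monotonically; segmented volume is
non-increasing in α.

If nothing around the seed exceeds the initial threshold (e.g. after complete
metabolic response) the lesion is declared non-delineable; the pipeline then
reproduces the baseline VOI on the post grid as a rigid translation supplied
by the caller (full landmark registration is out of scope). SUV statistics
are read from that fallback VOI, while MTV and TLG are recorded as 0 — there
is no metabolically active volume — flagged `metabolic_disappearance`. This
is what makes ΔTLG = −100% the exact signature of complete disappearance.

## Intensity features

SUVmax and SUVmean are the maximum and mean over the VOI. SUVpeak averages a
fixed 1-cm³ sphere (radius (3000/4π)^⅓ ≈ 6.204 mm); sphere membership is by
voxel-center-in-sphere, the sphere is not restricted to the VOI, and near the
grid edge the mean runs over the voxel centers that exist. The search
maximizes the sphere mean over every candidate center in the VOI ("the
highest-uptake part of the tumor"); fixing the sphere at the SUVmax voxel is
available via `mode="at_max"`. Because the sphere may contain voxels below
the maximum, SUVpeak ≤ SUVmax whenever the max voxel's sphere is the argmax,
but the contract does not require SUVpeak ≤ SUVmax in general.

MTV is voxel count × voxel volume (mL); TLG = SUVmean × MTV holds to 1e−9
relative by construction. Deltas are signed percent changes
100·(post − pre)/pre; a zero or missing baseline leaves the delta undefined
(NaN with a warning) rather than ±∞.

## Texture features

The VOI is quantized to G = 64 grey levels by masked min–max binning
(`level = min(G, ⌊G(v − min)/(max − min)⌋ + 1)`, constant region → level 1).
Min–max rather than fixed-bin-width was chosen because it makes all six
features exactly invariant under positive affine transforms of the raw SUV —
a property the tests verify. The three matrices are built over the 13 unique
one-voxel displacements (the lexicographically positive half of the
26-neighbourhood) and aggregated into a single matrix before any
normalization:

* GLCM: ordered voxel pairs, counted in both directions, normalized once to
  probabilities. Entropy uses log base 2 (values over a 64-level matrix then
  land in the single-digit bit range typical of published PET radiomics).
* GLRLM: maximal constant-level runs per direction; a mask gap breaks a run.
* GLSZM: maximal 26-connected constant-level zones (direction-free).

HGRE, ZLNU and SZHGE use the standard N_r / N_z normalizations. The 3-D
matrices are implemented here (established image libraries provide only 2-D
co-occurrence), and each is verified against an independent brute-force
oracle — exhaustive pair enumeration, line-walking run scans, BFS flood
fill — on randomized small volumes and on all 512 two-level 3×3 patterns.

Two consequences of the conventions worth noting: a strict two-level 3-D
checkerboard forms exactly two GLSZM zones under 26-connectivity (diagonal
equal-parity voxels touch), not one zone per voxel; and at 4 mm spacing the
SUVpeak sphere contains 19 voxel centers (center + 6 face + 12 edge-diagonal
neighbours at 4√2 ≈ 5.66 mm).

## Shape features

Elongation generalizes the minimum-bounding-rectangle edge ratio to 3-D: the
foreground voxel centers (physical mm) are projected onto their principal
axes (eigenvectors of the point-cloud covariance) and the ratio of the
longest to shortest bounding-box edges is returned. Each extent includes the
projection of one voxel box onto its axis, so a one-voxel-thick rod has a
finite, large elongation and a single voxel gives exactly 1 on an isotropic
grid; a digital sphere gives 1 within ±0.02 at radius 10 voxels. A 2-D
in-plane variant (`mode="slice2d"`, richest slice) is provided; the 3-D box
is the default.

Sphericity π^⅓(6V)^⅔/A and compactness V/(√π·A^{3/2}) take both V and A from
a marching-cubes iso-surface at 0.5 of the (zero-padded) binary mask. A
voxel-face surface would overestimate A by tens of percent and bias
sphericity far below 1 even for perfect spheres; and taking V from the voxel
count while A comes from the smoothed mesh can push sphericity above 1 on
small blocky masks, so both quantities come from the same closed mesh — the
isoperimetric inequality then guarantees sphericity ∈ (0, 1] for every mask,
with equality only in the spherical limit. Masks below 8 voxels are not
meshable and are rejected (the pipeline records NaN shape features for such
lesions instead of dropping the patient). The compactness formula is one of
several "first-form" conventions in use; its absolute values are not
comparable across software.

## Response classification

Metabolic response uses SUVpeak changes with the standard ±30% relative and
±0.8 absolute thresholds: PMD for a new lesion or a qualifying increase, CMR
for post SUVpeak at or below the background reference, PMR for a qualifying
decrease, SMD otherwise, with precedence PMD > CMR > PMR > SMD — the four
categories partition the input space and are monotone toward CMR as post
uptake falls. The background reference is supplied by configuration.
Histologic response dichotomizes the Salzer-Kuntschik grade at III/IV
(<10% vs ≥10% viable cells).

## Survival simulation and prognostic screening

Cohorts follow a Weibull proportional-hazards model: with baseline scale λ
and shape k, event times are drawn by inversion,
T = λ(−log U / e^η)^{1/k}, with linear predictor η = β·x using raw covariate
values (so a fitted Cox coefficient estimates β per covariate unit).
Censoring is independent Uniform(0, t_max) with t_max calibrated by bisection
so the expected censored fraction matches the target; at n = 1000 the
empirical event fraction lands within ±5 points of the target. Defaults:
λ = 1500 days, k = 1.2, 30% censoring — a five-year-median-follow-up regime
with events concentrated in the first two years, as is typical for pediatric
bone sarcoma. The default covariate model (binary lung/bone metastasis flags
with prevalences around 23%/15%, a lognormal shape feature centered near 1.5)
is this package's choice of a realistic presentation; no distributional claim
is inherited from any specific cohort.

Cox fits are maximized by Newton–Raphson with the Efron correction for ties
(via `lifelines`); monotone-likelihood separation surfaces as a warning flag
on the fit rather than silent divergence. The multivariate model includes
only candidates with univariate Wald p ≤ 0.10 ("significant or nearly
significant"); excluded candidates are reported as not retained. Continuous
features enter untransformed by default, with optional median
dichotomization, since either convention is defensible and neither is claimed
to match any particular study. Wald p-values are reported; no
multiple-testing correction is applied by default (a screening, not a
confirmatory, analysis). Simulation checks: 95% CI coverage on 100 cohorts
(n = 400, binary covariate, true HR 5.684, 30% censoring) falls in [88, 99]%
with mean log-HR bias below 0.05.

Spearman correlation (mid-ranks, t-approximation p) relates feature deltas to
the regression grade; detection performance reports per-class sensitivity and
specificity with exact Clopper–Pearson intervals.

## Pipeline and problem sizes

`run_study` processes each manifest row independently (per-patient errors are
logged and the run continues), writes `features.csv`, `deltas.csv`,
`response.csv`, `prognostics.csv` and a JSON run manifest sufficient to
reproduce the run, and is bit-deterministic under a fixed seed and config.
Patients lacking a post-chemotherapy study participate in baseline prognostic
models only. The bundled study simulator defaults to 60 patients on 36³ grids
at 3 mm spacing — large enough for stable texture matrices and mesh-based
shape features, small enough that a full simulate-and-analyse cycle completes
in well under a minute; tests use 25–32 voxel grids for the same reason.

## What the synthetic data does not show

Phantoms are ellipsoids with stylized textures on a flat background: passing
tests demonstrate correctness of the computational contracts (geometry,
matrix construction, model fitting, determinism), not clinical performance on
real FDG-PET, where irregular lesion margins, heterogeneous background organs,
partial-volume effects, scanner harmonization and registration error all
matter. The survival simulator encodes a proportional-hazards world; it
cannot validate the proportional-hazards assumption itself, and no
diagnostics (Schoenfeld residuals, time-varying effects) are provided.
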