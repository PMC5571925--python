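# petsarc

Quantitative FDG-PET analysis for pediatric bone sarcoma (Ewing sarcoma and
osteosarcoma): lesion segmentation, radiomic feature extraction at baseline
and after neoadjuvant chemotherapy, metabolic response classification, and
prognostic survival screening — with synthetic phantom and cohort generators
so every stage is testable without patient data.

## Who this is for

Imaging scientists and biostatisticians who want a reproducible, fully tested
re-implementation of the classic PET-radiomics prognostic workflow used in
bone-sarcoma studies: delineate the tumor VOI on an SUV image, extract
intensity / texture / shape metrics, compute percent changes after
chemotherapy, classify metabolic response, and screen every metric against
progression-free and overall survival with Cox proportional-hazards models.

## What it computes

**Intensity & volume** (on a body-weight SUV volume restricted to the VOI):
SUVmax; SUVmean; SUVpeak = max over candidate centers of the mean SUV in a
fixed 1-cm³ sphere (radius ≈ 6.204 mm); MTV (mL) = foreground voxels × voxel
volume; TLG = SUVmean × MTV. Percent changes Δf = 100·(f₂ − f₁)/f₁.

**Texture** (after 64-grey-level min–max quantization of the VOI, matrices
aggregated over the 13 unique one-voxel 3-D displacements):

- GLCM → homogeneity Σ p(i,j)/(1+|i−j|), entropy −Σ p log₂ p (bits),
  dissimilarity Σ |i−j| p(i,j)
- GLRLM → high grey-level run emphasis HGRE = (1/N_r) Σ r(i,l)·i²
- GLSZM (26-connected zones) → ZLNU = (1/N_z) Σ_s (Σ_i z(i,s))²,
  SZHGE = (1/N_z) Σ z(i,s)·i²/s²

**Shape** (mask geometry only): elongation = longest/shortest edge of the
principal-axis bounding box of the voxel-center cloud (1 = maximally
symmetric); sphericity = π^⅓(6V)^⅔/A ∈ (0,1]; compactness = V/(√π·A^{3/2}),
with V and A from a marching-cubes iso-surface.

**Segmentation**: iterative adaptive thresholding
T_{k+1} = α·mean(region_k) + β·background from T₀ = 0.4·SUVmax(seed region),
returning the connected component containing the seed; a non-delineable
post-therapy lesion falls back to the translated baseline VOI.

**Response**: PERCIST-style CMR/PMR/SMD/PMD from SUVpeak (±30% and ±0.8
thresholds, precedence PMD > CMR > PMR > SMD); histologic responders are
Salzer-Kuntschik grades I–III (<10% viable cells).

**Prognostics**: univariate Cox PH per covariate (Efron ties), multivariate
fit over covariates with univariate p ≤ 0.10, Spearman correlation of deltas
with the regression grade, and staging detection sensitivity/specificity with
exact binomial CIs.

## Worked example

```python
import petsarc as ps

# a 28 mm noise-free spherical lesion (SUV 8) on background 1
spec = ps.PhantomSpec(
    grid_shape=(32, 32, 32), spacing=(2, 2, 2), semi_axes=(14, 14, 14),
    lesion_suv=8.0, background_suv=1.0, noise_sd=0.0, background_noise_sd=0.0,
)
baseline, post = ps.generate_response_pair(spec, uptake_scale=0.4)
vol0, truth0 = baseline

seg = ps.adaptive_segment(vol0, (15, 15, 15), background=1.0)
print(seg.mask.n_voxels, truth0.n_voxels)   # 1472 1472  (exact recovery)
print(round(seg.threshold, 2))              # 5.0  = 0.5*lesion_mean + background

f0 = dict(zip(("suv_max", "suv_mean"), ps.suv_basic(vol0, seg.mask)))
vol1, _ = post
seg1 = ps.adaptive_segment(vol1, (15, 15, 15), background=1.0)
f1 = dict(zip(("suv_max", "suv_mean"), ps.suv_basic(vol1, seg1.mask)))
print(ps.delta_percent(f0, f1, features=("suv_mean",)))  # {'suv_mean': -60.0}

print(ps.percist_classify(ps.suv_peak(vol0, seg.mask),
                          ps.suv_peak(vol1, seg1.mask), background_ref=1.0))  # PMR
```

A 60% uptake reduction is recovered exactly on the noise-free phantom and is
classified as a partial metabolic response.

A full synthetic study (paired images for 60 patients, clinical table,
feature/delta/response/prognostics reports) runs from the shell:

```sh
petsarc simulate --out study --n-patients 60 --seed 7
petsarc run --config study/config.yaml
```

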