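# Methods

`petscore` re-implements, as a fully tested pipeline, an integrated
tumor+host prognostic analysis for FDG PET/CT in pancreatic cancer: primary-
tumor radiomics after adaptive-threshold segmentation, bone-marrow (BM) FDG
uptake quantification, maximally selected chi-square dichotomization, Cox /
Kaplan–Meier survival modelling, and a 0–4 prognostic score. Because no
patient data are available, every stage is driven by synthetic generators
that plant a known ground truth; this note records the models, conventions
and design choices, and what the synthetic validation does and does not
establish about real data.

## Imaging substrate

PET volumes are 3D arrays of standardized uptake values (SUV, dimensionless)
with physical voxel spacing in mm; regions (manual VOIs, tumor delineations,
vertebrae, liver) are boolean masks on the same grid. NIfTI is the on-disk
format (nibabel).

## Tumor segmentation (Nestle adaptive threshold)

Within a manually drawn VOI:

    threshold = 0.3 × mean{SUV(v) : SUV(v) > 0.7 × max SUV} + mean background SUV

and the tumor is every VOI voxel with SUV ≥ threshold. Conventions:

* The hot-voxel set uses strict `>` at 70% of the VOI maximum (the maximum
  voxel always qualifies); the final mask and all isocontours use `≥`, so
  ties at a cutoff are kept.
* "Background" is not intrinsically defined by the formula. The default
  helper takes a 2-voxel-thick shell around the VOI, excluding voxels above
  70% of the VOI maximum (to avoid lesion spill-in). The background mask is
  always an explicit argument, so callers can substitute their own region.
* No connected-component filtering is applied to the mask; margin curation
  is a manual step in practice and out of scope here.
* An empty-tumor error is raised only when the threshold actually exceeds
  the VOI maximum (no voxel survives); a threshold exactly at the maximum
  keeps the maximum voxel under the `≥` rule.

Bone-marrow uptake: each vertebral VOI contributes the mean SUV within its
75%-of-maximum isocontour; BM SUV is the unweighted mean over the 1–6
vertebral values (fewer than six models the exclusion of degenerate
vertebrae). Liver uptake is the plain mean over the liver VOI — the
isocontour applies only to vertebrae. BLR = BM SUV / liver mean.

## Radiomics (41 parameters)

Counts: 4 conventional + 6 first-order + 31 higher-order (6 GLCM, 3 NGLDM,
11 GLRLM, 11 GLZLM). Named features beyond the family counts follow the
LIFEx v7 feature set.

* **Discretization.** Lesion SUVs are resampled into L = 64 relative levels
  on [0, lesion max]: `level(v) = min(L, floor(v/max·L)+1)` — left-closed
  bins of width max/L, top value clamped into bin L. Binning is per-lesion
  (no min–max window), so multiplying the volume by k > 0 leaves every
  discretized feature unchanged while SUVmax, SUVpeak and TLG scale by k and
  MTV is invariant.
* **Conventional.** SUVmax; SUVpeak = mean SUV over all volume voxels whose
  centres fall in a 1 cm³ sphere (radius ≈ 6.2 mm) centred on the hottest
  lesion voxel; MTV = voxel count × voxel volume (cm³);
  TLG = MTV × mean lesion SUV (g).
* **First-order.** Histogram entropy in bits (−Σ pᵢ log₂ pᵢ) and energy
  (Σ pᵢ²) over the 64 levels; skewness and kurtosis are the standardized
  third/fourth central moments of the discretized levels (kurtosis not
  excess-corrected). Shape: sphericity = (36πV²)^⅓ / A with A a mesh surface
  area, and compacity = A / (36πV²)^⅓, its reciprocal. The mesh comes from
  marching cubes after a light 0.5-voxel Gaussian anti-aliasing of the
  binary mask: a raw binary mesh overestimates smooth-surface area by ~9%
  (a radius-10 digitized ball scores 0.91 instead of ≈1), while heavier
  smoothing distorts small lesions; with 0.5 voxels the ball scores 0.96.
* **GLCM.** Co-occurrences of level pairs over the 13 unique 3D directions
  at distance 1, symmetrized, summed into one matrix before normalization
  (merged strategy; `glcm_mode="average"` offers per-direction averaging).
  Features: homogeneity, energy, contrast, correlation, entropy (bits),
  dissimilarity.
* **NGLDM.** For each lesion voxel with at least one in-mask 26-neighbour,
  the absolute difference between its level and the neighbourhood mean is
  accumulated per level. Coarseness, contrast and busyness follow the
  classical neighbourhood grey-level difference definitions.
* **GLRLM.** Runs of equal level counted per direction; the 11 run
  statistics (SRE, LRE, LGRE, HGRE, SRLGE, SRHGE, LRLGE, LRHGE, GLNU, RLNU,
  RP) are computed per direction and averaged over the 13 directions.
* **GLZLM.** Zones are 26-connected components of constant level; the same
  11 statistics over zone sizes (SZE … ZP), including zone length
  nonuniformity (ZLNU).
* **Missing policy.** Degenerate statistics (GLCM correlation of a
  single-level lesion, moments of a single voxel, NGLDM contrast/busyness
  with one grey level) are NaN — an explicit missing marker that propagates
  to output tables, never a silent zero.
* **Eligibility floor.** `extract_all` rejects lesions under 64 voxels;
  texture statistics on smaller supports are unstable and such lesions are
  excluded from analysis.

Every matrix and every higher-order feature is verified against a
brute-force enumeration oracle (explicit pair/run/zone walking in the test
suite) on random 4×4×4 arrays, exactly.

## Synthetic phantoms

A phantom places a spherical tumor, six spherical vertebral bodies and a
liver sphere in a 128 mm cube (64³ voxels at 2 mm isotropic by default),
with pairwise-disjointness enforced and a ≥64-voxel tumor floor. Default
mean SUVs echo a typical staging scan: tumor 6, marrow 1.74, liver 2.02,
background 0.5, additive Gaussian noise SD 0.05.

Tumor heterogeneity is a spatially correlated multiplicative texture: a
Gaussian random field (correlation length 6 mm) is standardized over the
tumor, mapped through the normal CDF to a bounded uniform amplitude
u ∈ [−1, 1], and applied as `SUV = mean·(1 + h·u)`, clipped at zero. The
bounded amplitude matters: with unbounded (Gaussian or lognormal)
amplitudes the lesion maximum grows faster than the spread, so
relative-binned histogram entropy stops increasing in h; with the bounded
amplitude the planted heterogeneity level and the extracted first-order
entropy stay monotonically linked across the working range (h ≈ 0–1.2),
which is the property the generator must provide to ground-truth the
texture chain. h = 0 renders an exactly homogeneous lesion.

One global seed fans out to fixed per-component substreams (tumor texture,
noise, cohort, registry) via `SeedSequence` spawn keys, so identical
spec+seed reproduce outputs bit-for-bit and adding a region does not
perturb the others.

What the phantoms do **not** emulate: anatomical shape, partial-volume and
reconstruction blur, respiratory motion, scanner-dependent noise texture,
or physiological background gradients. Passing phantom tests therefore
demonstrates that the *computational* chain is correct and internally
consistent — not that the features are accurate or reproducible on clinical
images.

## Synthetic cohorts

Survival follows an exponential proportional-hazards model: patient i has
hazard λ₀·exp(lpᵢ), with lpᵢ summing planted log-hazard-ratios of five
dichotomized indicators — BM SUV > 1.53, TLG > 41.40 g, first-order
entropy > 3.40, age > 65, stage III–IV. The exponential baseline is a
deliberate simplification (closed-form inversion, easy medians). Censoring
is exponential (default 0.01/month, loss to follow-up) truncated at an
administrative horizon of 61 months, the maximum follow-up of the
motivating cohort.

Default parameters are the study conditions: n = 65; effect sizes at the
published adjusted hazard ratios (BM SUV 4.30, TLG 2.37, entropy 2.89; age
and stage at modest 1.5 and 3.0); covariate distributions log-normal/normal
with the published medians and plausible spreads (BM SUV median 1.74, TLG
55.54, entropy centred at 3.40, age 66 ± 10, sex/stage/treatment at the
published frequencies). The baseline hazard (0.0024/month) is calibrated
once so the generated cohort's overall KM median OS is ≈14 months under the
default mix, matching the reported cohort. An optional Gaussian-copula
parameter links BM SUV and NLR (default 0: the motivating correlations
ρ ≈ 0.27 are reported but no generative link is stated, so none is
asserted).

The table carries the planted truth (`true_*_high` indicators and
`true_log_hazard`) for recovery tests. A closed-form helper gives the
expected censored fraction for the exponential+cutoff model and a bisection
calibrator solves for the censoring rate achieving a target fraction.

Note that with the calibrated default baseline, a cohort with only a single
planted effect is event-sparse over 61 months; recovery experiments
(cutpoint and hazard-ratio recovery, coverage) therefore use an event-rich
parameterization (baseline 0.05/month, censoring ≈15–20%) so the sampling
error of the estimators, not the censoring pattern, is what is being
tested.

The eligibility screen is modelled explicitly: five exclusion criteria
(no staging PET; supportive care only; prior malignancy; low-uptake tumor;
tumor < 64 voxels) applied in listed order, each patient tallied once under
the first matching criterion (the tally convention for multi-reason
patients is a design choice; the source does not state one). The default
registry plants 97 records with sequential exclusion counts 6/14/3/4/5,
leaving 65 eligible.

## Survival statistics

* **Spearman correlation**: scipy, average ranks for ties, two-sided p.
* **Maximally selected chi-square**: candidates are the observed values
  between the 10th and 90th percentiles (minimal-group protection: each
  side of a split must keep ≥3 subjects); each split "≤ c vs > c" is scored
  by the two-group log-rank chi-square, computed by a vectorized
  implementation over all candidates at once; the maximizing c is returned,
  ties toward the smaller cutoff. The log-rank variant is a choice (the
  chi-square-on-2×2-tables variant would also fit the name); the
  implementation cross-checks against an independent log-rank oracle. The
  naive χ²(1) p-value is reported alongside the Lausen–Schumacher
  selection-corrected p-value; downstream Cox p-values are *not* corrected
  for cutpoint selection (mirroring common practice), which is why the
  corrected value is surfaced for transparency.
* **Cox models**: lifelines `CoxPHFitter` (Efron ties) behind the module
  surface; univariable means one covariate plus age/sex adjusters,
  multivariable lists all covariates. Dichotomized covariates are coded
  0 (≤ cutoff) / 1 (> cutoff). Fewer than 10 events per model term warns;
  non-convergence or diverging coefficients (|β| > 20, the complete-
  separation signature) fails explicitly.
* **Harrell's C**: own implementation with the original pair conventions —
  a pair is usable when the shorter time has an event (or times tie with
  exactly one event, the censored subject being the longer survivor); risk
  ties count 0.5. Verified pairwise-exactly against lifelines'
  `concordance_index` on tied/censored data. CI by seeded percentile
  bootstrap over patients (default 1000 resamples when requested).
* **Kaplan–Meier**: lifelines product-limit fit; median = earliest time
  with S(t) ≤ 0.5, NaN when never reached; median CI by the
  Brookmeyer–Crowley construction (times where the pointwise survival CI
  brackets 0.5); horizon queries beyond the last observed time are answered
  by carrying the step function forward and flagged as extrapolation.

## Scoring system

Weights are fixed constants, not fitted: 1 point per tumor factor
(TLG > 41.40 g; entropy > 3.40), 2 points for the host factor
(BM SUV > 1.53); comparisons strictly `>` so boundary values score 0.
Totals 0–4 pool into prognostic groups "0–2", "3", "4". Cutoffs may be
taken as the published defaults or derived per cohort by the maximally
selected test (weights stay 1/1/2 either way). Evaluation: per-group KM
summaries and Cox hazard ratios against the "0–2" reference, Harrell's C of
the total score, and subgroup tables for the two fixed splits (stage I–II
vs III–IV; surgery vs other treatment). Empty groups are reported with
explicit markers, never dropped silently.

## Pipeline

A single JSON config drives the full run. The cohort generator plants each
patient's latent imaging parameters and survival; a phantom per patient is
rendered from those latent values (tumor radius from TLG at fixed tumor
mean SUV; heterogeneity increasing with planted entropy; vertebrae at the
patient's BM SUV) and pushed through segmentation, marrow measurement and
feature extraction, producing `*_measured` columns. The survival and
scoring analysis then runs on the planted columns — the analysis table —
exactly as the motivating study analyzed its measured table; the measured
columns exist to exercise and audit the imaging chain (e.g. measured BM SUV
tracks the planted value up to noise and isocontour selection). Per-stage
row counts, wall-clock and artifact SHA-256 hashes are recorded; identical
config+seed reproduce the artifacts byte-for-byte.

## Problem sizes used in the validation suite

Recovery and null-calibration experiments run at the sizes stated in their
tests: cutpoint recovery at n = 400 (±0.1 tolerance on the planted 1.53),
consistency of its error over n ∈ {100, 400, 1600}; hazard-ratio recovery
at n = 2000 (planted 2.0 within [1.8, 2.2]); estimator bias/coverage over
200 replicates at n = 500; concordance nulls over 100 replicates at
n = 500; KM median consistency at n = 5000 (true median 14.1 within
[13.4, 14.8]); stratification ordering at n = 2000. The null-model
hazard-ratio check runs at n = 6000 so its Monte-Carlo error is well inside
the [0.9, 1.1] band being asserted.

## Known limitations

* The exact 31-feature nomenclature of the motivating analysis is not
  public; family counts and the three named features (GLCM energy, GLCM
  entropy, GLZLM zone length nonuniformity) anchor the inventory, the rest
  follows LIFEx v7 conventions.
* Exponential survival and independent censoring are idealizations; no
  time-dependent covariates, competing risks, or proportionality
  diagnostics beyond the fit warnings.
* Phantom realism is deliberately minimal (see above); published
  patient-level results (median OS 14.1 months, C-index 0.793, table
  hazard ratios) are properties of an undeposited cohort and are used only
  as structural templates and configuration defaults, not as reproduction
  targets.
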