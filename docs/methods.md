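# Methods

This note documents the models, conventions and numerical choices behind
`lge_radiomics`: what each stage computes, which knobs matter, and what the
synthetic cohort does and does not establish about real LGE data.

## Scientific setting

In nonischemic dilated cardiomyopathy (DCM), late gadolinium enhancement
(LGE) CMR marks myocardial fibrosis, a substrate for ventricular
tachycardia/fibrillation. Presence and burden of LGE discriminate risk only
modestly; the hypothesis exercised here is that the *texture* of the
myocardium on LGE images — its roughness and heterogeneity, quantified by
radiomic features such as the GLCM autocorrelation — carries incremental
prognostic information beyond a clinical risk score and LGE presence/burden
for the endpoint of appropriate ICD therapy.

## Synthetic cohort generator

No patient images ship with the package; every downstream stage is
exercised on a seeded generator that reproduces the statistical structure
the analysis assumes.

**Geometry.** Each patient contributes `n_slices` short-axis slices sharing
one annular myocardium mask (inner/outer radii in mm on a grid with
configurable pixel spacing). Defaults: 64-pixel grids at 1.5 × 1.5 mm,
radii 24/32 mm — a dilated, thin-walled left ventricle at typical LGE
in-plane resolution.

**Texture model.** Masked pixels hold a Gaussian random field: white noise
convolved with an isotropic Gaussian kernel of width `h` (pixels), then
affine-mapped to mean 300, SD 50 arbitrary units over the mask. `h` is the
single roughness knob: `h = 0` gives i.i.d. pixels; larger `h` lengthens
the correlation length, which the extractor reads as a coarser texture with
higher GLCM autocorrelation. The mapping `h -> mean autocorrelation` is
empirically strictly increasing over the default range `h in [0.5, 4]`
(checked at 50 images per level). A Gaussian random field was chosen
because it is the simplest seedable generative model with exactly one
interpretable roughness parameter; real LGE texture is not claimed to be
Gaussian.

**Scar.** With probability 0.56 (the LGE prevalence typical of such
cohorts) a contiguous angular sector covering 5%–25% of the mask is
shifted by +400 a.u. (8 within-ROI SDs), making it detectable by the 5-SD
rule with burden close to the planted fraction. A reference
"normal-myocardium" sector is placed opposite the scar, mirroring the
clinical practice of sampling visually normal myocardium.

**Covariates.** Clinical covariates are drawn from independent marginals
loosely matched to a DCM primary-prevention population (age ~ N(58, 13)
truncated, male ~ Bern(0.61), AF ~ Bern(0.15), QRS ~ N(130, 35), hemoglobin
~ N(13.5, 1.6) with anemia = Hb < 12 g/dL, creatinine ~ N(1.1, 0.3) mg/dL).
Covariate covariance is deliberately not modelled: the clinical score is
exercised as plumbing and is uninformative for the simulated outcome by
construction, which makes the incremental value of the radiomic signature
easy to read.

**Outcomes.** Event times are exponential proportional hazards with
log-hazard `beta_texture * z(h) + beta_scar * scar` (defaults 0.7 and 1.07
per SD / per flag), administrative censoring at 8 years, and the baseline
hazard solved numerically (Brent root-finding) so the expected event
fraction equals the 15% target. Times are capped at the horizon and
strictly positive.

## ROI standardization

* Resampling to 1 × 1 mm by bilinear interpolation on a grid aligned with
  the input's physical frame (`out_size = round(n * spacing)`, positions
  past the last pixel centre edge-extended); masks use nearest-neighbour so
  they stay boolean.
* Min-max normalization to [0, 1] over masked pixels only. A constant ROI
  maps to all zeros rather than raising, so degenerate synthetic slices
  flow through with their constant-image feature values.
* Gray-level discretization into `Ng = 32` equal-width bins on [0, 1]
  (`level = min(floor(x*Ng)+1, Ng)`). A fixed bin *count* is the coherent
  choice after per-ROI min-max normalization; `Ng` is configurable.
* Normalization is per-slice by default (features are computed per slice
  and averaged, so a per-slice dynamic range is the natural companion);
  `ExtractionConfig(normalization="stack")` instead shares one min/max
  across a patient's slices (with the default per-slice re-normalization
  of filtered images, the shared bounds act on the original image type
  and its first-order statistics; disable `renormalize_filtered` to
  propagate them through the filters).
* LGE presence/burden: threshold = mean + 5 SD of the reference normal
  region (pooled across slices); burden = % of myocardial *pixels* above
  threshold pooled over slices — an area proxy for the clinical
  %-of-LV-mass figure, invariant to joint affine intensity rescaling.

## Filter bank

Eleven image types: original; exponential `e^x`; logarithm `ln(1+x)`
(finite at 0); square; square root; central-difference gradient magnitude;
rotation-invariant uniform local binary pattern (radius 1, 8 neighbours);
and the LL/LH/HL/HH subbands of a one-level 2D Haar decomposition,
nearest-neighbour upsampled back to the ROI grid. Haar keeps test
arithmetic exact; the wavelet family is configurable. Neighbourhood filters
see the masked mean outside the mask (no zero-background contamination at
the ROI border); masked pixels alone enter all statistics. Each filtered
image is re-min-max-normalized over the mask by default so a single
quantizer serves every image type (a flag disables this).

## Texture features

All matrices are 2D per slice with the four distance-1 directions (0°,
45°, 90°, 135°) pooled into one matrix before feature computation; a
neighbour pair counts only when both pixels are masked. Conventions worth
stating:

* GLCM is symmetric (each ordered pair counted both ways) and normalized
  after pooling. Correlation of a zero-variance matrix is defined as 1;
  logs are base 2 with `0 log 0 = 0`.
* NGTDM uses the masked 8-neighbourhood mean; pixels with no masked
  neighbour are excluded from `N`.
* GLRLM runs break at mask boundaries; `RunPercentage` divides the pooled
  run count by `n_voxels * n_directions` so it stays in (0, 1].
* GLSZM zones are 8-connected.
* GLDM dependence at distance 1 with tolerance `alpha = 0`; the dependence
  of a pixel is 1 + the number of matching masked neighbours (the centre
  counts, so the size axis starts at 1).
* First-order entropy/uniformity use the quantized histogram; the other
  first-order statistics use the continuous normalized values.

The full vector is 92 features per image type (18 first-order, 23 GLCM, 16
GLRLM, 16 GLSZM, 14 GLDM, 5 NGTDM) × 11 image types = 1,012 features,
named `imageType_family_Feature`. Feature definitions follow the standard
reference formulations rather than bit-matching any particular extraction
library; the GLCM path is additionally cross-checked in the tests against
scikit-image's `graycomatrix`/`graycoprops`, and every matrix builder
against a literal brute-force re-implementation. A patient's vector is the
unweighted mean over non-degenerate slices; a slice is degenerate when its
mask admits no neighbour pair.

## Signature construction

1. **Pruning** at |Pearson r| > 0.8, greedy: repeatedly drop the feature
   with the highest mean |r| over its currently violating partners (ties
   by name). This is deterministic and guarantees the survivor contract
   (no remaining pair above threshold). Constant columns have undefined
   correlations and are treated as uncorrelated.
2. **Consensus clustering** of the *features*: 500 resamples (default),
   each drawing 80% of the features without replacement, one
   average-linkage dendrogram on the `1 - Pearson` distance between
   feature columns per resample, cut at every k in 2..6. Consensus
   `M_k(i,j)` = co-clustered / co-sampled (0 if never co-sampled). Final
   per-k assignments come from average-linkage clustering of `1 - M_k`,
   the convention of the consensus-clustering literature. k = 1 is a
   degenerate partition and is not evaluated.
3. **k selection**: `A(k)` is the area under the empirical CDF of the
   upper-triangle consensus entries; `Delta(2) = A(2)`,
   `Delta(k) = (A(k) - A(k-1))/A(k-1)`. The visual "elbow" is made
   deterministic: chosen k = the largest k with
   `Delta(k) >= 0.25 * max Delta` (`elbow_fraction` configurable). On
   three planted correlated blocks this recovers k = 3 in ≥ 9/10 seeds.
4. **Medoids**: per cluster, the member minimizing the summed Euclidean
   distance to its cluster's members, computed on z-scored columns —
   without standardization the distance would be dominated by
   large-magnitude features. A `method="correlation"` variant (highest
   mean within-cluster correlation) is provided; the two can disagree, and
   the Euclidean argmin is primary.

## Clinical score

The published linear score
`-0.2*age + 4*male + 5*AF - 8*amiodarone + 7*pacemaker - 3*smoking
- 0.2*|QRS-130| - 8*anemia + 1.77*creatinine` (creatinine in mg/dL,
anemia = Hb < 12 g/dL). The nonsustained-VT and digoxin terms of the
original score are omitted, matching cohorts where those variables are
unavailable. No imputation: a missing field is an error.

## Risk models and evaluation

* **Discrimination** is logistic regression on event-by-end-of-follow-up
  (any event during follow-up; a fixed-horizon variant is a flag away),
  with predictors z-scored internally. Perfect separation or
  non-convergence falls back to a ridge-penalized fit, flagged.
* **Optimism correction** (the realization of "bootstrap-corrected
  C-statistic"): Harrell's scheme with the configured number of resamples
  (default 1000) — refit on each resample, optimism = mean(AUC on the
  resample − resampled model's AUC on the original data), corrected =
  apparent − optimism. The 95% CI takes percentiles of the original
  model's AUC over the resamples, shifted by the optimism and widened if
  necessary to contain the point estimate.
* **AUC** is the Mann-Whitney concordance with half credit for ties, so it
  is invariant to strictly monotone transforms of the risks.
* **DeLong** uses the structural-components (midrank) formulation; a
  zero-variance difference reports p = 1. Its type-I error at nominal 0.05
  is verified to land in [0.03, 0.07] over 2,000 null simulations.
* **Youden cutoff** scans the observed risk values with the rule
  `high iff risk >= t`, ties resolved to the lowest threshold (a tolerance
  of 1e-12 guards float noise in tied J values).
* **Continuous NRI** is category-free (any risk increase counts as up);
  CI by percentile bootstrap (default 2000 resamples, seeded); the p-value
  uses the bootstrap SE in a normal approximation. Categorical
  reclassification tables at a fixed cutoff label up-moves correct for
  events and down-moves correct for non-events.
* **Cox models** use lifelines (Efron ties) with Schoenfeld-residual
  proportional-hazards tests; **Kaplan-Meier** curves are compared by the
  log-rank test. The KM grouping feature is the signature member with the
  strongest univariate discrimination of the endpoint, dichotomized at its
  Youden cutoff computed on the same (development) cohort; a published
  cutoff for GLCM autocorrelation (3.93) is exposed as a constant but is
  cohort-specific and not a default for new data.
* The model grid pairs each base model (LGE presence, LGE burden, clinical
  score + either) with its radiomics-augmented counterpart, plus a
  radiomics-only model.

## Problem sizes

The test suite and the acceptance script use cohorts of 300 patients with
2 slices each (40 patients for the determinism check), 200–500 consensus
resamples, and 500–1000 bootstrap resamples; matrix-builder oracles run on
50 random 8×8 ROIs per family. These sizes give stable Monte-Carlo
behaviour for every property checked while keeping a full run in minutes
on one CPU.

## What passing tests do and do not show

The synthetic cohort demonstrates that the *pipeline* behaves as designed:
texture information planted in the hazard is recovered by the extracted
features, survives unsupervised signature construction, and shows up as
higher corrected AUC, positive NRI and separated KM curves. It does not
validate the clinical claim on real data: the generator's texture is
stationary Gaussian, scars are single contiguous sectors, covariates are
independent of outcome, and inter-vendor/field-strength intensity effects,
motion, partial-volume and contouring variability are all absent. Real
LGE radiomics must additionally survive those nuisances.

## Known limitations

* 2D per-slice analysis only; no 3D matrices, no shape features.
* The printed feature total of this implementation (1,012) reflects its
  own enumeration of the standard families; other extraction software
  enables slightly different feature subsets and discretization defaults,
  so absolute feature values are comparable only within one pipeline.
* The exact consensus matrices depend on the resampling RNG; only
  seed-fixed runs are bitwise reproducible.
* Exponential baseline hazard and administrative censoring only — adequate
  for parameter-recovery checks, not a model of clinical follow-up.
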