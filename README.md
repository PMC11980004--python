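# lge-radiomics

Texture radiomics of late gadolinium enhancement (LGE) cardiac MRI for
ventricular-arrhythmia risk stratification in nonischemic dilated
cardiomyopathy (DCM).

Patients with DCM who receive a primary-prevention ICD are selected almost
entirely on ejection fraction, yet only a minority ever receive appropriate
device therapy. LGE marks the fibrotic substrate of ventricular
tachycardia, but its mere presence or burden discriminates risk weakly.
This package implements, end to end, the analysis that asks whether the
*texture* of the myocardium on LGE images — roughness and heterogeneity
captured by gray-level co-occurrence statistics — adds prognostic value
beyond a clinical risk score and LGE presence/burden:

1. **ROI standardization** — resample each masked short-axis slice to
   1 × 1 mm (bilinear), min-max normalize intensities over the myocardium
   mask to [0, 1], discretize into Ng = 32 gray levels; LGE
   presence/burden by the clinical 5-SD rule
   (threshold = mean + 5·SD of normal myocardium).
2. **Filter bank** — the original image plus 10 filtered versions
   (exponential, gradient, logarithm, square, square root, local binary
   pattern, and the 4 subbands of a one-level Haar wavelet decomposition).
3. **Texture features** — first-order statistics and the GLCM, GLRLM,
   GLSZM, GLDM and NGTDM families (standard reference definitions;
   e.g. GLCM autocorrelation `Σᵢⱼ i·j·p(i,j)`), 92 features × 11 image
   types = 1,012 per patient, averaged over slices.
4. **Radiomic signature** — correlation pruning at |r| > 0.8, consensus
   hierarchical clustering of the features (80% subsamples, 1 − Pearson
   distance, average linkage), k chosen from the relative change of the
   consensus-CDF area, and one medoid feature per cluster
   (`x_medoid = argmin_y Σᵢ d(y, xᵢ)`, Euclidean on z-scored columns).
5. **Risk models** — logistic models over the grid {clinical score, LGE
   presence/burden} ± signature, graded by optimism-corrected C-statistics
   (1,000 bootstrap refits), DeLong tests, continuous net reclassification
   improvement, Cox proportional-hazards models with Schoenfeld checks,
   and Kaplan-Meier curves split at the Youden cutoff of the strongest
   signature feature.

Because no patient data can ship with the code, a seeded **synthetic
cohort generator** reproduces the data structure the analysis assumes:
annular myocardium masks, Gaussian-random-field texture whose roughness
parameter drives GLCM autocorrelation, contiguous hyperenhanced scars
detectable by the 5-SD rule, clinical covariates, and proportional-hazards
outcomes with a 15% event rate tied to texture and scar. See
`docs/methods.md` for every model and convention.

## Worked example

```bash
lge-radiomics run-all --seed 11 --out results/demo
```

or in Python:

```python
from lge_radiomics.pipeline import run_pipeline

report = run_pipeline({"n_patients": 300, "n_slices": 2, "seed": 11,
                       "out_dir": "results/demo"})
```

A 300-patient cohort (seed 11) prints, among other things:

```
event_rate            0.16
lge_prevalence        0.54
n_features            1012   -> 89 after pruning at |r| > 0.8
chosen_k              3
signature_features    exponential_firstorder_Maximum,
                      wavelet-LH_glcm_Id,
                      squareroot_glcm_DifferenceVariance
corrected AUC         clinical + LGE presence             0.63
                      clinical + LGE presence + radiomics 0.73   (DeLong p = 0.004)
continuous NRI        0.58  [0.29, 0.85]
KM log-rank p         2.9e-07  (signature feature split at its Youden cutoff)
```

Reading this: consensus clustering found 3 stable feature clusters
(matching the three planted sources of variation in the generator) and
picked one representative per cluster, blinded to outcome. Adding those 3
features to the clinical + LGE-presence model raised the
optimism-corrected C-statistic from 0.63 to 0.73, moved predicted risks in
the right direction for most patients (continuous NRI 0.58 > 0), and the
high/low split on the strongest signature feature separated
arrhythmia-free survival sharply — the qualitative headline of the
analysis. Artifacts land in `results/demo/`: `cohort.csv`, `features.csv`,
`signature.csv`, `model_grid_auc.csv`, `model_comparisons.csv`,
`consensus_cdf.csv`, plots and a `report.json` whose `results_hash` is
bitwise reproducible under a fixed seed.

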