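# gliograde

Grading gliomas from digital-pathology image patches. Low-grade gliomas
(LGG, WHO II–III) and high-grade gliomas (HGG, WHO IV) differ in histology:
high-grade tumors show denser, larger, more pleomorphic nuclei, stronger
spatial heterogeneity of the stained tissue, and necrotic foci. This
package quantifies those contrasts on grayscale slide patches and turns
them into a patient-level classifier:

1. **Patch extraction** — 1024×1024 (configurable) windows from a flat
   raster slide, kept when ≥ 50% of pixels are stained tissue and the
   saturated-pixel fraction is small; Rec. 601 luma grayscale conversion.
2. **Conventional features (26)** — 16 whole-patch statistics (mean, SD,
   median, skewness, kurtosis, min/max, deciles P10–P90) and 10 morphology
   features (area, perimeter, eccentricity, convex area, Euler number,
   orientation, compactness 4πA/P², major/minor axis, boundary edge
   sharpness) averaged over nucleus-like connected components from a
   two-cluster K-means intensity split (dark cluster = nuclei).
3. **Texture features (18)** — after quantization to 16 gray levels, eight
   Haralick statistics of the distance-1 gray-level co-occurrence matrix
   (contrast Σ(i−j)²p(i,j), correlation, energy, homogeneity, entropy,
   cluster shade/prominence, autocorrelation) and ten Galloway run-length
   statistics of the gray-level run-length matrix (SRE, LRE, RLN, GLN,
   HGLRE, LGLRE, SRHGLE, SRLGLE, LRHGLE, LRLGLE), computed in the four
   principal directions and averaged.
4. **Layered linear SVMs** — patch features averaged per patient and joined
   with clinical covariates (age, gender), giving layers conventional (26),
   texture (18), clinical (2). Seven models over layer subsets
   (Ia/Ib/Ic one layer, IIa/IIb/IIc two, IIIa all three) are evaluated by
   stratified 10-fold CV with, inside each training fold only, z-scaling,
   greedy SVM forward feature selection (inner 5-fold) and a C grid search
   over 2^−5…2^5. Pooled test-fold scores give accuracy, sensitivity,
   specificity (HGG positive) and AUC.
5. **Permutation comparison** — each model re-run over permuted row
   orderings; paired AUC differences between models summarized by their
   mean, 2.5th–97.5th percentile interval and an empirical p-value;
   a difference is significant when the interval excludes zero. Features
   are ranked by Cohen's d (positive = higher in HGG).

Because real cohorts of graded slides are not redistributable, the package
ships a synthetic cohort generator (`gliograde.synthetic_cohort`) that
emulates the LGG/HGG contrasts — darker elliptical nuclei on bright stroma,
with class-dependent density, size, elongation, boundary jaggedness,
intensity heterogeneity, necrosis-like holes, and a class age gap — so the
whole pipeline runs and is tested end to end without any download.

## Worked example

```python
from gliograde import (CohortConfig, generate_cohort, patch_feature_table,
                       aggregate_patient_features, run_cv)

cfg = CohortConfig(n_patients=30, hgg_fraction=0.5, patches_per_patient=4,
                   patch_size=96, seed=7)
patches, clinical = generate_cohort(cfg)
patch_df = patch_feature_table(patches)
table = aggregate_patient_features(patch_df.drop(columns=["patch_id"]), clinical)
res = run_cv(table, "IIIa", outer_folds=5, seed=0)
print(f"IIIa accuracy {res.accuracy:.1f}%  AUC {res.auc:.3f}")
```

prints

```
IIIa accuracy 100.0%  AUC 1.000
```

— with the default class contrasts the three-layer model recovers every
patient's grade: the generator's separation is strong by construction
(image-feature effect sizes of several SD). The clinical-only model Ic,
which sees just the ~13.6-year age gap, reaches roughly 75% accuracy /
AUC ≈ 0.8 on the same cohorts, and shuffling the grade labels drops IIIa
to chance (40–60%).

The same stages are scripted in `analysis/01_simulate_cohort.py` …
`04_compare_models.py`, which write their tables under `results/`, and are
available as a CLI (`gliograde simulate|extract|features|train|compare|all`).

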