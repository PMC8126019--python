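# glioradiomics

Radiomics analysis of glioblastoma (GBM) tumor subregions on multiparametric
MRI, as a tested, reproducible Python pipeline.

GBM lesions are heterogeneous: a necrotic core, a contrast-enhancing solid
part, peritumoral tissue and peritumoral edema behave differently on the four
routine MR contrasts (T1-CE, T2-WI, T2-FLAIR, ADC) and respond differently to
therapy. This package asks the quantitative version of the radiologist's
question: *given a labeled subregion on co-registered multiparametric MRI, do
its imaging features identify which tissue compartment it is?* It is aimed at
researchers in quantitative neuro-oncology imaging who want a transparent,
fully seeded re-implementation of this analysis that runs on synthetic
phantoms — no patient data required.

## What it computes

For every (subject, subregion) ROI a **1316-dimensional feature vector**: a
329-feature block per modality, over the four modalities,

| family | per modality | total | content |
|---|---|---|---|
| first-order | 16 | 64 | histogram statistics of voxel intensities |
| LBP histogram | 16 | 64 | statistics of rotation-invariant uniform LBP codes (P=8, R=1) |
| shape | 8 | 32 | volume, surface area, surface-to-volume ratio, sphericity, spherical disproportion, maximum 3D diameter, elongation, flatness |
| GLCM | 22 | 88 | Haralick-family co-occurrence statistics, 4 in-plane directions, distance 1 |
| GLRLM | 11 | 44 | classic run-length statistics (SRE, LRE, GLN, RLN, RP, ...) |
| SIFT | 256 | 1024 | element-wise mean ⊕ sd of pooled 128-d keypoint descriptors |

Gray levels are discretized per ROI to 64 fixed-count bins before texture
matrices are built; texture is accumulated slice-wise (axial) and averaged
over the 0°/45°/90°/135° direction set.

The feature table is then classified with **leave-one-out cross-validation**
(kNN, Gaussian naive Bayes, random forest with n_trees = 500 and 8 candidate
features per split, and an MLP), with per-fold standardization and optional
exhaustive grid search. The 4-class problem is dissected one-vs-rest into
per-class recall = TP/(TP+FN), precision = TP/(TP+FP),
F1 = 2·P·R/(P+R), accuracy = (TP+TN)/(TP+FP+TN+FN) and ROC/AUC. Finally,
features are ranked by seed-averaged random-forest importance scores (IS),
the top 20 selected, and their Pearson/Spearman correlation structure against
the region label computed.

Because patient MRI cannot be shipped, the package includes a first-class
**phantom generator**: cohorts of subjects carrying four nested ellipsoidal
subregions with controllable per-region, per-modality intensity profiles
(mean, noise, texture correlation length, histogram skew), a `separation`
knob in [0, 1] scaling inter-region profile contrast, and per-subject
geometry jitter. See `docs/methods.md` for the model and its limitations.

## Worked example

```python
from glioradiomics import (PhantomSpec, generate_cohort, ClassifierSpec,
                           loocv, rank_importance)
from glioradiomics.features import extract_cohort_features

spec = PhantomSpec(
    grid_shape=(36, 36, 24),
    semi_axes=((3.5, 3.0, 2.5), (6.0, 5.0, 4.0), (9.0, 8.0, 6.0), (12.5, 11.0, 8.5)),
    n_subjects=8, separation=1.0, seed=42,
)
table = extract_cohort_features(generate_cohort(spec))
print(f"feature table: {table.shape[0]} ROIs x {table.shape[1] - 2} features")

result = loocv(table, ClassifierSpec(family="random_forest", seed=42))
print(f"RF LOOCV overall accuracy: {result.metrics.overall_accuracy:.3f}")
for region in result.classes:
    print(f"  {region:<12} recall={result.metrics.recall[region]:.2f} "
          f"precision={result.metrics.precision[region]:.2f} "
          f"AUC={result.metrics.auc[region]:.2f}")

ranking = rank_importance(table, top_k=5)
print("top-5 features by RF importance:")
for name in ranking.top_k:
    print(f"  {name}")
```

prints

```
feature table: 32 ROIs x 1316 features
RF LOOCV overall accuracy: 0.969
  necrosis     recall=1.00 precision=0.89 AUC=1.00
  solid        recall=0.88 precision=1.00 AUC=1.00
  peritumoral  recall=1.00 precision=1.00 AUC=1.00
  edema        recall=1.00 precision=1.00 AUC=1.00
top-5 features by RF importance:
  ADC_glcm_Contrast
  T1CE_firstorder_RootMeanSquare
  FLAIR_glcm_Idn
  FLAIR_glcm_Contrast
  ADC_glcm_DifferenceVariance
```

Each of the 8 phantom subjects contributes 4 subregion ROIs (32 samples); at
full profile separation the forest recovers the subregion labels almost
perfectly from intensity and texture, and the highest-ranked features are the
contrast-like texture statistics that the generator's per-region correlation
lengths directly control.

The same analysis is available from the shell:

```bash
glioradiomics simulate --out cohort/ --seed 1
glioradiomics extract  --manifest cohort/cohort_manifest.csv --out features.csv
glioradiomics classify --features features.csv --model rf --seed 1 --out results/rf
glioradiomics analyze  --features features.csv --top-k 20 --out results/analysis
```

Mask label codes: 1 = necrosis, 2 = solid part, 3 = peritumoral tissue,
4 = peritumoral edema, 0 = background. Cohorts lacking a modality (e.g. no
ADC map) are handled in degraded mode (`--modalities T1CE,T2W,FLAIR`); the
vector then scales as 329 × n_modalities (987 for three contrasts).

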