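# Methods

## Problem setting

The pipeline classifies the four tissue compartments of a glioblastoma
lesion — necrosis (label 1), solid enhancing part (2), peritumoral tissue
(3), peritumoral edema (4) — from co-registered multiparametric MR volumes
(T1-CE, T2-WI, T2-FLAIR, ADC) plus an expert label mask. Segmentation
itself is out of scope: masks are inputs. The unit of analysis is one
(subject, subregion) ROI; a cohort of N subjects with all four regions
yields 4N samples for leave-one-out cross-validation (LOOCV).

## Phantom cohort model

Real patient volumes cannot be redistributed, so validation runs on
synthetic cohorts designed to carry the statistical structure the analysis
assumes: regions that differ in per-modality intensity distribution and
in spatial texture.

**Geometry.** Four nested ellipsoidal shells around a common center;
voxels take the label of the innermost shell containing them, so regions
2–4 are shell annuli around the solid necrotic core. Default grid
64×64×32 voxels at 1×1×1 mm (isotropic spacing makes shape features
hand-checkable); default semi-axes (6, 5, 3.5), (10, 8.5, 5.5),
(14, 12, 8), (19, 16, 11) voxels. Per subject, each semi-axis is jittered
uniformly by ±10% and the center by ±2 voxels, drawn from the subject's
own seed stream; gaps between consecutive shells are validated at
construction so strict nesting survives any jitter draw. Shape features
therefore vary across subjects (without jitter LOOCV on geometry would be
degenerate). A shell that rasterizes to zero voxels is a hard error naming
the region.

**Appearance.** Each (region, modality) pair has a profile
(mean, noise sd, texture correlation length, histogram skew), all in
arbitrary intensity units. The voxel field of a region is skew-normal
white noise smoothed with a Gaussian kernel of width equal to the
correlation length, re-standardized to unit variance, scaled by the noise
sd and shifted to the mean. Gaussian smoothing of white noise is the
simplest controllable autocorrelation model and gives the GLCM/GLRLM/LBP
families genuine signal to detect. Default means follow the qualitative
contrast logic of GBM MRI — enhancing solid part bright and necrosis dark
on T1-CE, necrosis bright on ADC (inverted with respect to T1-CE, so the
modalities are not redundant copies), edema bright on FLAIR; correlation
lengths grow inside-out (0.6, 1.0, 1.4, 1.8 voxels) and skew parameters
differ per region. These profiles are free parameters of the generator,
chosen once as plausible contrast patterns; they are not calibrated to any
patient data.

**Separation.** A scalar s ∈ [0, 1] linearly interpolates every profile
parameter between its across-region mean (s = 0) and its declared value
(s = 1). At s = 0 all four regions share a single voxel-value
distribution; at s = 1 they carry full contrast.

**What the phantom does *not* emulate**, and the resulting caveat for null
experiments: no MR physics (bias fields, partial volume, registration
error, vendor-dependent intensity scales), and — importantly — *geometry
is not exchangeable between regions*. Nesting forces the compartments to
differ systematically in size and shape at any separation: the core is a
solid ellipsoid while the others are annuli, and volumes grow inside-out.
Shape features and size-dependent intensity features (e.g. first-order
Energy = Σx²) therefore identify the region label even at s = 0, and a
classifier on the full 1316-feature vector stays far above 4-class chance
there. The meaningful no-signal control on this phantom is the
label-permutation null (shuffling region labels across samples drives
LOOCV accuracy into the binomial interval around 0.25), which the test
suite exercises. Passing recovery tests on phantoms shows the pipeline
detects the structure the generator plants; it does not certify
patient-data performance.

## Feature extraction

**Discretization.** Fixed-bin-count over the ROI's [min, max] with 64
levels by default: level = ⌊(x − min)/(max − min)·64⌋ + 1, clipped to
[1, 64]; a constant ROI maps to level 1. Monotone by construction.
Normalization is per ROI (per modality), not per volume — the common
field default at the 64-bin granularity of the first-order histogram.

**First-order (16).** Mean, median, min, max, range, variance (population
convention), sd, skewness, excess kurtosis, energy, entropy (bits, on the
64-bin discretized histogram), uniformity, RMS, mean absolute deviation,
10th and 90th percentiles. Zero-variance convention: skewness = kurtosis
= 0 and variance = sd = 0 on a constant patch (avoids catastrophic
cancellation in the moment routines).

**LBP (16).** Rotation-invariant uniform codes, P = 8 samples on a
radius-1 circle (10 possible codes), computed per axial slice on the
discretized patch. Each slice is edge-replicated by one pixel so every
masked pixel has a full neighborhood; codes are pooled over slices at the
masked positions (slices with fewer than 9 in-region pixels are excluded)
and summarized by the same 16 statistics under `LBP_`-prefixed names.

**Shape (8).** Volume = n·voxel volume. Surface area: marching cubes at
level 0.5 on the 0.5-voxel-Gaussian-smoothed mask (removes most staircase
bias: a digital ball of radius 10 measures sphericity ≈ 0.96 instead of
0.91 on the raw binary mesh); regions too small or thin for a stable
smoothed isosurface fall back to counting exposed voxel faces. Since any
true surface obeys the isoperimetric inequality, the estimate is clipped
from below at the equal-volume sphere's area, so sphericity ∈ (0, 1] and
spherical disproportion = 1/sphericity ≥ 1 always. Maximum 3D diameter
via the convex hull of voxel centers (pairwise fallback for degenerate
hulls). Elongation = √(λ₂/λ₁) and flatness = √(λ₃/λ₁) from the
eigenvalues (λ₁ ≥ λ₂ ≥ λ₃) of the voxel-coordinate covariance with each
voxel's own cell extent (spacing²/12) added to the diagonal — a single
voxel or a 1-voxel-thick rod keeps strictly positive axes instead of
collapsing to 0/0. The shape sub-block is repeated in each modality block
(the mask is shared), keeping the per-modality layout uniform at 329.

**GLCM (22) / GLRLM (11).** Built slice-wise on the axial decomposition —
clinical MR is anisotropic through-plane, so in-plane offsets are the
meaningful ones — with distance-1 offsets at 0°, 45°, 90°, 135°. Only
pixel pairs (runs) entirely inside the mask contribute; runs break at mask
gaps. Co-occurrence counts are symmetrized, pooled over all slices, then
normalized per direction; run counts are pooled per direction and conserve
the pixel count (Σ count·length = pooled in-region pixels). The 22 GLCM
statistics (autocorrelation, joint average, cluster prominence/shade/
tendency, contrast, correlation, difference average/entropy/variance,
dissimilarity, energy, entropy, homogeneity 1, homogeneity 2, IMC1, IMC2,
IDMN, IDN, inverse variance, maximum probability, sum entropy) and the 11
classic run statistics are computed per direction and averaged over the
four directions (a set closed under 90° rotation, so direction-averaged
features are invariant to in-plane right-angle rotations). Degenerate
conventions: correlation-type features are 0 when the gray-level variance
vanishes; entropies use 0·log 0 = 0. The name registry exported by
`glioradiomics.features.export_registry` is the normative feature list.

**SIFT (256).** Keypoints are detected per slice on the ROI patch
(intensities rescaled to [0, 1] by the ROI-wide range, background zero);
descriptors whose keypoint lies inside the mask are pooled over slices and
summarized by the element-wise mean and population sd of the 128-d
descriptors. This fixed aggregation was chosen over a learned bag-of-words
codebook deliberately: a codebook fitted on the cohort would leak
information across LOOCV folds, whereas mean ⊕ sd is deterministic and
fold-independent. A flat ROI with no keypoint anywhere yields the zero
vector with a logged warning; slices with an extent under 8 pixels are
skipped (below the SIFT scale-space minimum).

## Classification

One row = one (subject, subregion) ROI with its 4-class label; per-slice
classification with a majority-vote roll-up (>50% threshold, ties broken
by highest mean class probability) is available as a separate utility.
Every LOOCV fold fits a StandardScaler plus classifier on the training
rows only — corrupting a held-out row provably cannot change that fold's
model (tested). Folds whose training set loses a class are logged and
scored with the remaining classes.

Families and defaults: kNN (k = 5, euclidean; grid k = 1..30 ×
{euclidean, manhattan, minkowski}); Gaussian naive Bayes (continuous
features); random forest (500 trees, 8 candidate features per split;
grid: candidate features 100..2000 step 100 capped at the table width,
depth unlimited/10..110 step 10); MLP (two hidden layers 128/64, early
stopping, max 300 iterations — a modest default since nothing forces a
particular architecture at n ≈ 92). Grid search is exhaustive with LOOCV
overall accuracy as the criterion and ties broken by declared grid order,
so results are seed-reproducible.

Metrics follow the one-vs-rest dissection above; AUC is the rank
(Mann-Whitney) statistic with midrank tie handling, undefined (None, with
a warning) for a class lacking positives or negatives. Zero-denominator
metrics are reported as 0 and flagged. Overall accuracy is
trace/total of the multiclass confusion matrix, which for LOOCV equals the
mean of per-fold accuracies.

## Feature ranking and correlation

Importance scores are mean-impurity-decrease importances of forests fitted
on the full table, averaged over 10 seeds (single-forest rankings are
noticeably seed-dependent at p = 1316 ≫ n), re-normalized to sum to 1, and
ranked with ties broken by registry order. The top 20 features are
correlated pairwise and against the region label, encoded ordinally 1–4 in
the anatomical inside-out order (necrosis → solid → peritumoral → edema);
both Pearson's r and Spearman's ρ are reported, since only the latter is
invariant under monotone feature transforms. Zero-variance columns get
coefficient 0 and a flag. The heatmap export is a pure rendering of an
already-computed matrix.

## Problem sizes and determinism

The shipped study conditions are 23 subjects × 4 regions = 92 ROIs on the
64×64×32 grid (≈ 2 s to generate and ≈ 2 min to featurize end to end);
unit tests run on a 36×36×24 variant with identical structure. Every
stochastic component (phantom geometry and noise, forest construction,
MLP initialization) is driven by explicit integer seeds; the same seed
reproduces feature CSVs and metrics JSON byte-for-byte.

## Known limitations

- Phantom realism: no bias fields, no registration error, no scanner
  effects; profiles are plausible but uncalibrated. High phantom accuracy
  is a recovery check, not a clinical performance claim.
- Region geometry is intrinsically label-informative (see above), so
  "identical regions" null experiments require label permutation rather
  than `separation=0` alone.
- The 16 first-order and 22 GLCM statistic lists are one standard choice
  among several in the radiomics literature; the exported registry is the
  package's normative definition.
- Texture is 2D in-plane only; fully 3D offset sets are out of scope.
- No wavelet/filtered feature classes, no survival modeling, no
  significance testing with multiplicity control for the correlation
  matrices.
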