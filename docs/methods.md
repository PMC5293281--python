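# Methods

`dceradiomics` implements, as a tested pipeline on synthetic phantoms, a
radiomic analysis of bilateral-breast DCE-MRI for predicting the four
molecular subtypes of breast cancer (luminal A, luminal B, HER2-over-
expressing, basal-like). A case consists of a precontrast volume S-0 and two
postcontrast volumes S-1, S-2 on a common grid (default voxel spacing
0.625 × 0.625 × 1.2 mm), a tumor seed point, two clinical covariates (age,
menopausal status) and a subtype label. The pipeline registers the series,
segments the breast region and the tumor, extracts a 90-element feature
vector per case, selects features with a genetic algorithm, and classifies
subtypes one-against-others under leave-one-out cross-validation (LOOCV).

## Synthetic phantoms

No patient imaging ships with the package; every experiment runs on
generated phantoms with known ground truth.

Geometry: two breast half-ellipsoids attached to a bright chest-wall/body
slab occupying the posterior ~22% of the grid (default 96 × 96 × 24 voxels);
background air is zero plus sensor noise. Parenchyma carries multiplicative
log-normal texture (a Gaussian random field smoothed with σ = (2, 2, 1)
voxels, exponentiated at amplitude 0.22). An ellipsoidal tumor with
lobulated boundary (radius field perturbed by a smooth noise field at
amplitude 0.18) sits in one breast, in-plane radii 5–7.5 voxels, 2.5–4
slices thick.

Kinetics: postcontrast series are S-0 scaled voxel-wise. Tumor voxels get
multiplier 1 + (u_T − 1)·h_i where u_T is the subtype's uptake at time T
and h_i = max(1 + d·g_i, 0.05) is a per-voxel heterogeneity factor with
dispersion d and g_i drawn from a standardized gamma with target skewness
(luminal A: d = 0.06, skew 0.2; luminal B: d = 0.30, skew 1.8; HER2:
d = 0.15, skew 0.8; basal: d = 0.15, skew 0.8). Parenchyma gets
1 + b·ramp_T·w_i where b is the subtype's background-parenchymal-
enhancement (BPE) level per side (HER2 0.30/0.30; basal 0.14/0.12;
luminals 0.10/0.08), ramp = (0.8, 1.0) at S-1/S-2 and w_i a smooth random
field normalized to [0, 1] per breast. These presets plant the qualitative
contrasts the pipeline should recover — low tumor skewness/kurtosis for
luminal A versus luminal B, and the highest contralateral-breast
enhancement for HER2 — and are test fixtures, not biological claims.

Additive Gaussian sensor noise (σ = 8 against a parenchymal baseline of
300) is applied per series; S-1 and S-2 are then translated by integer
in-plane shifts drawn uniformly in [−3, 3] voxels. Ages are drawn in
29–78 with menopausal status assigned by a logistic curve centered at 50.

What the phantoms do not emulate: coil inhomogeneity and bias fields,
fat-suppression behavior, pharmacokinetic (Tofts-type) time curves,
deformable inter-series motion, rib/heart anatomy, partial-volume fat.
Passing recovery tests therefore demonstrates the internal consistency of
the algorithms at realistic contrast and noise, not clinical performance.

## Registration

Four steps per series, following the translational ("linearly shifting")
model: (1) Sobel gradient magnitude of each S-0 slice; (2) the
maximum-information window — the 32 × 32 patch with the largest summed
gradient energy, ties to the lexicographically smallest corner; (3)
exhaustive Pearson-correlation matching of that window against the moving
slice over all integer displacements within a radius of 10 voxels (ties:
smallest Euclidean shift, then lexicographic; zero-variance windows score
0); (4) the per-slice estimates are aggregated by the median into one
integer in-plane translation per series, applied with edge replication.
Integer shifts keep subtraction maps free of interpolation blur. Median
aggregation over per-slice estimates makes the transform robust to the
occasional low-texture slice; a median at the search boundary logs a
warning because the true shift may exceed the search radius.

## Segmentation

Breast region: a 3-class Otsu quantization of S-0 separates air,
parenchyma and the bright chest-wall/body slab. Per sagittal column the
anterior edge of the rearmost contiguous high-intensity run defines the
chest-wall boundary (median-smoothed, 5-voxel window); tissue anterior to
it is split at the x midline into left/right compartments. This heuristic
is phantom-grade; pectoral-muscle delineation on clinical data is harder
and out of scope.

Tumor: the input is the enhancement map S-1 − S-0 (configurable to raw
S-1). On the seed slice a two-class spatial fuzzy C-means (FCM) runs over
the breast-masked values: fuzzifier m = 2, spatial weight α = 0.5 blending
each voxel's intensity-driven membership with the mean membership of its
in-plane 8-neighborhood, tolerance 1e-4. Centroids are seeded at the
background median and the mean enhancement of the 3 × 3 patch around the
seed — with a small bright lesion against a large background, quantile
initialization reliably converges to a split of the background instead.
If the converged centroid gap is below 0.15 × the mean breast S-0
intensity, the seed is declared to sit in non-enhancing tissue and
segmentation aborts (the negative-control contract).

The hard FCM labels are refined by a binary Markov-random-field pass:
Gaussian class likelihoods with an Ising smoothness prior (β = 1.0),
optimized by iterated conditional modes in 8 parity phases (one per
(x%2, y%2, z%2) triple) so that no two simultaneously updated voxels are
26-neighbors and the energy is provably non-increasing per sweep. The two
class likelihoods share a pooled variance: with free per-class variances a
broad tumor class claims moderately enhancing parenchyma that is an
outlier under the tight background class, which floods the mask.

Slice propagation realizes the adaptive cross-slice coupling: each
adjacent slice is warm-started with the previous slice's component, the
class statistics are re-estimated on the previous slice (where the labels
are trusted), and the search is confined to a 2-voxel dilation of the
component. Propagation stops when the in-slice component vanishes; the
final mask is the 26-connected component containing the seed.

## Feature vector (90 values)

Indices follow a fixed schema (`feature_schema()`): 1–2 clinical (age,
menopausal status); 3–17 tumor first-order per series (skewness, kurtosis,
max, mean, sd — population moments, kurtosis non-excess so a normal sample
tends to 3, constant regions 0 by convention); 18–22 morphologic; 23–37
tumor GLCM texture per series; 38–48 tumor kinetics; 49–63 BPE texture;
64–81 BPE kinetics (lesion side then contralateral); 82–90 bilateral
differences. Within each block the order is fixed image-major (S-0, S-1,
S-2) then statistic, so index-based reporting is stable across runs.

Morphology: volume = voxel count × voxel volume; radial lengths run from
surface voxels (≥ 1 face-neighbor outside) to the centroid in mm; diameter
is twice the mean radial length, radius sd its dispersion, roughness the
mean absolute radial deviation over the mean. Compactness is the
sphericity 36πV²/A³ (sphere → 1) with A the marching-cubes mesh area of
the mask after a 1-voxel Gaussian anti-aliasing of the indicator — meshing
the raw binary mask overestimates a smooth surface's area by ~10%
(staircase facets), and raw face counting by ~50%, which would make a
sphere score ~0.3.

Texture: gray-level co-occurrence (GLCM) over 3D regions. Intensities are
linearly quantized to 32 levels over the region's min–max; co-occurrences
accumulate over the 13 unique unit-displacement 3D offsets into a single
matrix (both voxels inside the region), symmetrized and normalized.
Haralick statistics: contrast Σp(i−j)², correlation
Σp(i−μᵢ)(j−μⱼ)/(σᵢσⱼ) (0 if either marginal is degenerate), energy Σp²,
homogeneity Σp/(1+|i−j|), entropy −Σp·log₂p. A single-level region returns
the degenerate single-cell values (0, 0, 1, 1, 0).

Kinetics: subtraction maps S-1−S-0, S-2−S-0, S-2−S-1 and relative
enhancement r = (I_T − I_0)/I_0 (defined where I_0 exceeds 1e-6 × the mean
S-0 intensity). Tumor block: mean/sd/max of each subtraction map over the
mask plus the mean voxel-wise ratios (S-2−S-0)/(S-1−S-0) and
(S-2−S-1)/(S-1−S-0), guarded to voxels with |S-1−S-0| above the epsilon;
if no voxel qualifies the ratio features are 0 with a logged warning.

BPE: eligible voxels are the breast compartment minus the tumor. They are
ranked by relative enhancement at S-1, descending, ties broken by voxel
index; the top ceil(1% · n) voxels (configurable p%) form the BPE region
per side. The 18 BPE kinetic features are mean/sd/max of each subtraction
map over that region, lesion side then contralateral; the 9 bilateral
features are their element-wise lesion-minus-contralateral differences.
The 15 BPE texture features are GLCM statistics of the whole lesion-side
parenchyma per series: the schema allocates a single 15-slot texture block
(one side), and the lesion side carries the tumor-associated parenchymal
signal; the kinetic block is the one that covers both sides.

## Feature selection and classification

Classifier: one binary ridge-logistic model per subtype versus the rest,
fitted by iteratively reweighted least squares on per-fold standardized
features (zero-variance columns dropped per fold), ridge 1e-8 chosen for
separability, linear predictor clipped at ±30, 12 Newton iterations (a
non-separable fit converges well within this; under separation further
iterations only inflate the coefficient norm without changing rankings).
Fits are class-balanced (positives and negatives carry equal total
weight): under leave-one-out, removing a case shifts the training
prevalence of its own class, and an unweighted one-vs-rest intercept then
systematically anti-ranks the held-out class, biasing null AUCs far below
0.5; balancing pins the intercept to the 50/50 operating point. Class
probabilities are the per-class sigmoids normalized to sum 1 (they rank
classes; they are not prevalence-calibrated).

Evolutionary search: generational GA over 90-bit inclusion chromosomes
with tournament selection (size 2), single-point crossover (probability
0.6), per-bit mutation (0.01), elitism of one, population 500 and 200
generations at study scale (tests and the acceptance script run a reduced
population 60 / 40 generations). Initial chromosomes include each feature
with probability 0.1: sparse subsets generalize better at n = 60 and are
cheaper to score. Fitness is the prevalence-weighted mean one-vs-rest AUC
of the classifier under stratified 5-fold cross-validation — training-set
AUC overfits the selection, and LOOCV is too slow inside a GA; a
training-set-AUC variant remains available in config. Search stops after 20
stagnant generations; an all-zero chromosome gets one random bit forced
on; everything is deterministic given the seed.

LOOCV with inner wrapper selection: each case is held out once; on the
remaining cases greedy forward selection over the EA pool adds the
candidate that most improves the cross-validated fitness, stopping below a
1e-4 improvement floor; the classifier is refit on the selection and the
held-out probabilities recorded. A fold that selects nothing (possible on
signal-free data) predicts the uniform distribution — predicting training
prevalence would anti-rank the held-out case's own class (the leave-one-out
prevalence artifact) and bias the null AUC well below 0.5. Per-feature
selection frequencies over folds form the selection-frequency table.

ROC/AUC: Mann–Whitney with ties counted half; 95% confidence intervals
and paired comparisons by DeLong's method. Overall AUC is the
class-prevalence-weighted mean of one-vs-rest AUCs, with the unweighted
mean reported alongside ("overall AUC" admits both conventions, and the
two diverge under class imbalance). Operating points maximize
(sensitivity + specificity)/2 over all score midpoints, ties to the lower
threshold. The Kruskal–Wallis screen is tie-corrected with chi-square
p-values; all-identical inputs return H = 0, p = 1.

## Problem sizes and determinism

Tests and the acceptance script use: 20 phantom seeds for registration
recovery, a 20-case cohort for segmentation Dice, a 60-case planted
feature table (signal only in features 3, 40, 83 at effect 1.2 sd) with 10
GA seeds for selection recovery, 20 label permutations for the null band,
and 200 replicates for type-I calibration. All randomness flows from
explicit integer seeds through `numpy.random.SeedSequence`; repeated runs
are bit-identical.

## Known limitations

The chest-wall heuristic, noise model and kinetic presets are
phantom-grade by construction. The negative-control check (seed in a
non-enhancing breast) keys on the FCM centroid gap and can pass a seed
placed in strongly enhancing parenchyma of a high-BPE case.
Selection-frequency tables and AUCs computed here characterize the
pipeline's behavior on phantoms and planted feature tables; they say
nothing about performance on clinical cohorts, which would require real
imaging data this package does not ship.
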