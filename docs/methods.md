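# Methods

## The grading problem and the pipeline's model of it

Histologic glioma grading separates low-grade (WHO II–III) from high-grade
(WHO IV) tumors using features a pathologist reads from H&E sections:
cellularity, nuclear size and pleomorphism, necrosis, and the overall
spatial disorder of the tissue. The pipeline encodes these as three feature
layers computed from grayscale slide patches — whole-patch intensity
statistics plus nuclear morphometry (conventional, 26 features), GLCM/GLRLM
texture (18 features), and clinical covariates (age, gender) — and treats
grading as a binary patient-level classification with linear SVMs trained
on layer subsets. The unit of prediction is the patient: patch features are
averaged per patient before modeling, which assumes patches are exchangeable
samples of one tumor and discards within-slide heterogeneity beyond what
the texture statistics capture per patch.

## Patch extraction

Tissue is stained and therefore dark; background glass is near-white. A
candidate window qualifies when the fraction of pixels darker than
`tissue_threshold` (default 220/255) is at least `min_tissue_fraction`
(default 0.5) and the fraction at or above the saturation level (default
250) is at most 0.05 — the saturation rule is an automated stand-in for the
manual artifact screening that real curation involves, and makes no claim
to detect pen marks, folds or blur. Candidate origins are sampled uniformly
at random (seeded) with rejection, falling back to a full grid scan when
random search stalls, so small or sparsely covered slides are still fully
explored. Origins are unique; windows may overlap. Tumor-vs-normal
discrimination within a slide is out of scope: the tissue filter accepts
any stained region.

## Conventional features

The 16 statistics are computed over all pixels; skewness and kurtosis are
standardized third/fourth central moments (kurtosis non-excess), both
reported as 0 on a zero-variance patch so feature matrices stay finite.
"Deciles" are the 10th–90th percentiles with linear interpolation.

Morphometry needs a foreground. Pixel intensities are split by two-cluster
1-D K-means initialized at the 25th/75th intensity percentiles — the
initialization makes the split deterministic, and for k=2 the resulting
threshold is equivariant under adding a constant to all intensities. The
darker cluster is taken as the nuclear foreground (hematoxylin-dark
chromatin); components are 8-connected, and only components with area
*strictly greater* than `area_threshold` (default 100 px) are retained.
Per-component area, perimeter, eccentricity, convex area, Euler number
(8-connectivity), orientation, axis lengths (from second moments),
compactness 4πA/P², and edge sharpness are averaged over components.
Orientation is reported as the signed angle of the major axis from the
image horizontal, in (−90°, 90°]. Edge sharpness has no canonical
definition; here it is the mean Sobel gradient magnitude over the boundary
pixels of each component, which rises when nuclear borders are crisp
against the stroma. A patch whose segmentation retains no component raises
a typed error and is dropped (with a warning) by the feature-table builder.

## Texture features

Patches are quantized to 16 equal-width levels spanning the patch's own
[min, max]; per-patch normalization makes texture robust to stain-intensity
shifts at the cost of making the features scale-free (a patch and a
contrast-stretched copy quantize identically; the adaptive range is
recorded here as a deliberate choice). A constant patch maps to level 0.

The GLCM uses offset distance 1 in each of the four principal directions
(the distance-1 neighbors are exactly a pixel's 3×3 neighborhood along
those directions), is symmetrized, then normalized. Entropy uses log₂ with
0·log 0 = 0; correlation of a zero-variance GLCM is defined as 1 so the
feature stays finite on flat patches. The GLRLM counts maximal equal-level
runs along each direction's scan lines (rows, columns, or diagonals); the
emphasis statistics index gray levels 1-based so the low-gray-level terms
are finite at level 0, with Nr the total run count. All 18 features are
averaged over the four directions, which makes the vector exactly invariant
to 90° rotations and to horizontal/vertical flips — a property the tests
verify numerically against brute-force pair/run-counting oracles.

## Models and cross-validation

Layer membership is encoded in column prefixes (`conv_`, `tex_`, `clin_`),
so a model spec is just a set of layers plus a selection flag; the
clinical-only model Ic skips selection (two features). Gender is encoded
male=1/female=0; HGG is the positive class, so sensitivity measures
detection of the aggressive tumor — the clinically alarming call.

Outer evaluation is stratified 10-fold CV, seeded. Everything fitted —
feature-wise z-scaling (zero-SD features centered only), greedy forward
selection, the C grid search over 2^µ for integer µ ∈ [−5, 5], and the
final linear SVM — sees the training fold only; the tests include a
leakage audit asserting bitwise-identical decision scores when test-fold
labels are corrupted. Forward selection always takes the best single
feature, then adds the feature maximizing inner 5-fold accuracy while the
best gain exceeds 0.001 (the "steady state" tolerance; ties go to the
earlier column). Inner C tuning breaks ties toward the smaller C (wider
margin). Metrics are pooled over test folds — one confusion matrix and one
score vector — rather than fold-averaged; at desk-scale cohorts the pooled
estimate is markedly stabler.

## Permutation comparison

"Re-running the model on a permuted dataset" means re-shuffling the row
order, which changes the stratified fold assignment while keeping the true
labels (label permutation would destroy the real-model AUCs the comparison
is about). Iteration t of every model uses seed base+t for both the
permutation and the CV split, so differences between two models are paired
per iteration and fold-assignment noise partially cancels. The summary is
the mean difference, the 2.5th–97.5th percentile interval, and an add-one
empirical p-value with ties counted half, p = (1 + #{d<0} + ½#{d=0})/(n+1)
— the tie convention makes two identical run sets report p = 0.5 rather
than 1.0. Significance is declared from the interval excluding zero; the
p-value is reported alongside.

A calibration caveat, demonstrated by this package's own experiments: under
a dataset-level null (two models on independent noise layers, labels
shuffled once), the percentile interval spans only fold-reshuffle noise
while the paired differences share a persistent dataset-level offset, so
the interval-excludes-zero rule rejects far above nominal (measured ≈ 0.5–0.7
across cohort sizes 20–80 at 200 iterations). The criterion is therefore a
descriptive summary of run-to-run variability, not a calibrated hypothesis
test; conclusions about model differences should rest on effect size and
replication, not on this significance flag.

Feature discriminability is ranked by Cohen's d with pooled SD; positive
values mean higher in HGG. Cross-run AUC correlation between models is
Pearson's r of the paired AUC vectors and is undefined (reported NaN with a
warning) when a model's AUCs are constant — which on the default synthetic
cohort happens for all image-layer models, since they sit at the AUC
ceiling.

## Synthetic cohort generator

The generator emulates what the features measure, not what tissue looks
like. Per class it draws darker elliptical "nuclei" (count Poisson at
`nucleus_density` per 10⁴ px; size, elongation and intensity normal around
class means; orientation uniform; boundaries roughened by a low-order
random Fourier perturbation scaled by `edge_jaggedness`) on a bright
stroma, adds optional necrosis-like bright foci and i.i.d. Gaussian noise,
and clips to 8 bits. Defaults (LGG → HGG): density 8 → 14, major axis
16 → 24 px, axis ratio 1.3 → 2.0, nuclear intensity 90 → 70, noise SD
8 → 20, necrosis rate 0 → 0.3, jaggedness 0.05 → 0.25; stroma 200 for
both. Nucleus sizes were set so single nuclei clear the default 100-px
component-area threshold. Clinical defaults mirror the population the
generator stands in for: HGG fraction 349/735, ages normal with means
43.19 (LGG) and 56.79 (HGG), SD 10 (no published SD; 10 years is a
realistic clinical spread), 58% male, gender uninformative unless a
log-odds shift is configured. Patients are patch bundles: each patient
draws `patches_per_patient` independent patches from its class parameters;
slide-level granularity (one raster per patient, patches via the
extractor) is available through `generate_slide` and is exercised in tests,
but the default path skips the raster for speed since downstream consumes
patch statistics only.

What passing tests on this generator do **not** show: robustness to stain
variation, scanner artifacts, rotation at non-90° angles, within-tumor
heterogeneity between patches, tumor/normal admixture, or realistic
feature correlations — the synthetic class gap is strong by construction
(several SD on many features), so image-layer models saturate at AUC 1.0.
The generator validates the machinery (features measure what they claim,
CV leaks nothing, comparisons behave as specified), not clinical
performance.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale chosen as the package's
own defaults for a laptop-class single CPU: 96×96 patches (nucleus counts
per patch stay in the tens), cohorts of 20–100 patients, 3–10 patches per
patient, 15–25 permutation iterations for comparisons, and the calibration
experiment at 50 replicates × 200 iterations with a single C and no
selection (the calibration property concerns the comparison statistic, not
the inner model search). Oracle-equivalence tests run exact comparisons
(integer counts; features to 1e-9 relative). Degenerate inputs are handled
by convention rather than NaN wherever a finite default is defensible:
zero-variance skewness/kurtosis → 0, zero-variance GLCM correlation → 1,
zero pooled SD effect size → 0 with warning; undefined correlation stays
NaN because no finite value is defensible there.
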