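# Methods

## Model

Detection is cast as two-class pixel classification: ω₁ = microcalcification
(MC), ω₂ = healthy tissue.  Each pixel carries a 4-vector
x = [graylevel, local-max rank, wavelet highpass, ED₈], and each class is a
4-D Gaussian N(mⱼ, Cⱼ).  With equal priors, the class score is the
log-posterior up to a constant shared by both classes,

    dⱼ(x) = −½ ln|Cⱼ| − ½ (x − mⱼ)ᵀ Cⱼ⁻¹ (x − mⱼ),

and a pixel is labeled MC iff d₁(x) > d₂(x) strictly — exact ties go to
healthy, so a detection always requires positive evidence.  The score is a
quantity to be *maximized* (it is a log-density); descriptions of this rule
as a "minimum distance" refer to the Mahalanobis term alone and would invert
the determinant correction, so the implementation maximizes dⱼ throughout.

The Gaussian assumption is the method's central approximation.  Its known
failure mode, visible in any heavy-tailed texture, is that joint tail events
of the healthy class (singular-looking texture points) fall "between" the
two Gaussians and are absorbed by whichever class has the wider covariance —
usually the MC class.  The physiology filter (below) exists largely to
absorb this.

## Self-learning

No labeled lesion archive is used.  Training pixels come from the analyzed
image itself:

- **MC class**: a binary *standard model* — clusters of small filled discs —
  is blended into the image and the feature vectors at exactly the model
  pixels become the ω₁ training set.  Blending assigns each model pixel an
  additive boost equal to K times its own graylevel, smoothed by a 3×3
  Gaussian H (σ = 0.8): hybrid = I + conv(K·I·M, H).  Smoothing the *added
  layer* (rather than re-smoothing the whole hybrid under the model support)
  makes the operation exactly the identity at K = 0 and keeps every pixel
  outside the dilated model support bit-identical to the input; both
  properties are load-bearing for testing and for the locality guarantee.
- **Healthy class**: two disjoint square ROIs (side ⌈√(4300/2)⌉ = 47 px)
  placed uniformly at random inside the breast, avoiding the dilated
  standard model and any annotated lesion circles.  Two separate regions
  sample the nonstationary texture better than one; the healthy set must be
  ≥3× the MC set (with the defaults it is ≈50×, 4418 vs ≈90 pixels).

Covariances are the unbiased sample estimates; if the smallest eigenvalue
falls below ε·trace/4 (ε = 1e-6) a ridge of that size is added.  A channel
with exactly zero variance (a perfectly flat ROI) is refused with an error
naming the channel: silently regularizing it would hide a degenerate
training set.

## Modeling constant K

K sets the brightness of the synthetic lesions relative to local tissue and
is the framework's main tuning parameter.  Dense-glandular tissue, where
real MCs have low contrast, needs small K (default 0.2); fatty tissue takes
larger K (default 0.5).  Without a tissue hint, breast-region variance above
400 (graylevels²) selects the dense rule.  The per-channel interclass mean
differences and variance ratios, plus the normalized mean difference
NMD = (mean graylevel over model pixels − mean over breast)/255, are exposed
as a diagnostic: very large gaps mean the classifier will track the
synthetic tone (missing real, dimmer MCs), very small gaps mean weak
separation and many false detections.

## Features

- x1 graylevel: raw intensities, kept on the [0, 255] scale — the decision
  function is affine-covariant through Cⱼ, so no standardization is applied.
- x2 local-max rank: #{strictly smaller neighbors}/(w²−1) in a w = 9 window,
  replicate padding; equals 1 exactly at strict local maxima and is
  invariant to monotone intensity remappings.
- x3 wavelet highpass: 2-level separable db4 DWT, symmetric extension;
  deepest approximation zeroed; inverse transform cropped to the input
  shape.  Values are signed; the magnitude is available but the signed
  response is the default.
- x4 ED₈: sum of absolute differences to the 8 neighbors, replicate padding.

Replicate padding avoids the spurious border singularities zero padding
would create.  Borders remain the least trustworthy rows/columns; the
pipeline handles the breast outline separately (below).

## Post-processing

1. **Breast mask**: Otsu's threshold on the original graylevel histogram
   (exhaustive 256-candidate scan of the between-class variance, smallest
   maximizer on ties), then the largest 8-connected foreground component
   with holes filled.  Detections outside the mask are vetoed.
2. **Border suppression**: the intensity ramp at the breast outline
   misclassifies as a connected band; any detection component intersecting
   the 5-px ring just inside the mask is removed whole.  Removing whole
   components (not masking pixels) avoids fragmenting the band into many
   isolated false "detections".
3. **Plant erasure**: the synthetic plants are training material, not
   findings; everything within 14 px of the standard model is erased from
   the detection mask.  The radius must cover the plants' wavelet-highpass
   halo — a level-2 db4 response extends roughly two filter lengths beyond a
   point feature — or each plant leaves a detectable ring around a blank
   core.
4. **Cluster physiology rule**: clinically, an MC cluster is ≥3
   calcifications within 1 cm² (a 50×50-px block at 200 µm/pixel).  The
   image is tiled into non-overlapping blocks and a detection component
   survives iff its centroid's block holds ≥3 component centroids.  The
   rule is idempotent and never adds detections.  A sliding-window variant
   was considered and rejected as the default to keep the evaluation tiling
   and the filter tiling identical.

## Evaluation protocol

Non-overlapping 50×50 tiling (residual rows/columns beyond the last full
block are dropped; 1024 = 20·50 + 24).  Blocks intersecting an annotated
lesion circle are excluded from the healthy census.  Each annotated region
scores TP if ≥1 detected component centroid lies inside its circle, else
FN — a detected "location" is a component centroid, so a 10-pixel blob
counts once.  Remaining blocks: FP iff ≥3 centroids, else TN.  Sensitivity
and specificity are percentages; undefined metrics (zero denominators) are
reported as absent rather than NaN.  The 87×87 variant flips the FP rule to
a single detected component per block.  By default all non-annotated tiles
are counted (including tiles outside the breast); passing a breast mask
excludes fully-outside tiles instead — both censuses are reported by the
CLI.

## Phantom generator

The phantom emulates what the evaluation needs and nothing more: a
half-elliptical breast (semi-axes 0.45·h, 0.70·w, attached to the left
edge) of correlated Gaussian texture — white noise smoothed with a Gaussian
of σ = 10 px (2 mm, glandular-structure scale) and rescaled to the tissue
preset — on a dark background (level 10, sd 2), with optional bright
rectangular marker.  Presets: fatty mean 120/sd 12, dense mean 170/sd 25
(calibration constants preserving the ordering that dense tissue is
brighter and more variable).  Planted clusters default to 6 discs of radius
1–2.5 px within a 15-px radius, additive contrast 70 graylevels smoothed at
the edges; contrast 70 keeps the per-phantom NMD at or above 0.1 for both
presets.

The texture correlation length matters more than it may appear: placing the
full tissue variance at the lesion spatial scale (~3 px) would tile the
breast with lesion-sized, lesion-amplitude blobs and make planted clusters
undetectable for any method.  A coarse (2 mm) field keeps the tissue
variance off the lesion scale, which is also what makes real MCs visible to
radiologists.

What the phantom does **not** model: film-grain noise, ductal/linear
structure, pectoral muscle, skin line thickness, MC shape irregularity
(malignant vs benign morphology), or intensity nonuniformity.  Passing the
phantom study therefore demonstrates the pipeline's internal consistency —
self-learning, classification, and the block protocol working together
against known truth — not clinical-grade performance on film; in
particular, pixel-scale noise on real film raises both classes' singularity
channels and will cost specificity relative to phantom numbers.

## Study sizes and determinism

The standard study runs ten 512×512 phantoms (five fatty at K = 0.5, five
dense at K = 0.2, three clusters each) — large enough for ~100 evaluation
blocks per image and stable aggregate rates, small enough to iterate on
freely.  All randomness flows from one master seed through
`numpy.random.SeedSequence` spawning (phantom texture, cluster placement,
standard-model geometry, ROI placement), so every result in the README and
the acceptance output is bit-reproducible from its seed.

## Known limitations

- Equal priors and a hard argmax; no per-pixel confidence output.
- The MC covariance is learned from synthetic lesions whose appearance is
  controlled by K; lesions much dimmer than K·I or with strongly
  non-disclike morphology are out of the trained class.
- Background ROIs may land on unrepresentative tissue; explicit ROI boxes
  can be supplied through the config for that case.
- If a synthetic plant happens to be placed over an unannotated real
  lesion, the plant-erasure step will hide that lesion for the run
  (annotated lesions are protected by the exclusion zones).
- Annotation circles are treated as ground truth for TP/FN; the protocol
  inherits whatever positional error the annotations carry.
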