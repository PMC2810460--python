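# mcdetect

Detection of clustered microcalcifications (MCs) in digital mammograms —
tiny bright calcium deposits, 0.1–1 mm across, whose clusters are among the
earliest mammographic signs of breast cancer.  The package implements a
single-stage, *self-learning* detection framework aimed at researchers in
mammography CAD: instead of training on a labeled archive of lesions, the
classifier synthesizes its own lesion-class training samples directly into
the image under analysis.

## Method

Each pixel is described by a four-channel feature vector

    x = [x1, x2, x3, x4]ᵀ

with **x1** the graylevel, **x2** the local-maximum rank (fraction of the
9×9 neighborhood strictly below the pixel), **x3** the wavelet highpass
response (image reconstructed from the detail subbands of a 2-level db4
decomposition with the coarse approximation zeroed), and **x4** the
point-singularity measure ED₈ = Σ |I(i+k₂, j+k₁) − I(i, j)| over the
8-connected neighborhood.

Training is self-supervised.  A binary *standard model* of synthetic MCs
(clusters of ≥3 small discs) is blended into the mammogram: each synthetic
pixel receives an additive boost K·I(i,j), smoothed by a small Gaussian
kernel H — the *modeling constant* K ∈ (0, 1] controls how bright the
synthetic lesions are relative to local tissue (≈0.2 for dense-glandular
tissue, ≈0.5 for fatty).  The lesion class ω₁ is trained on the synthetic
pixels of this hybrid image; the healthy class ω₂ on two randomly placed
background ROIs (≈4300 pixels, at least 3× the lesion set).  Both classes
are modeled as 4-D Gaussians and each pixel is scored with the equal-prior
log-posterior

    dⱼ(x) = −½ ln|Cⱼ| − ½ (x − mⱼ)ᵀ Cⱼ⁻¹ (x − mⱼ),

labeling a pixel as MC iff d₁(x) > d₂(x).  Post-processing removes
detections outside the Otsu-derived breast mask and applies the cluster
physiology rule: detected components survive only if their 50×50-pixel
block (1 cm² at 200 µm/pixel) holds ≥3 component centroids.  Evaluation is
block-based: sensitivity = 100·TP/(TP+FN) over annotated lesion regions and
specificity = 100·TN/(TN+FP) over healthy blocks, plus false-positive
blocks per image (an 87×87 single-detection variant is included for
comparison with older protocols).

A phantom generator provides ground truth: half-elliptical breasts with
correlated Gaussian tissue texture (dense-glandular brighter and more
variable than fatty) and planted MC clusters with known coordinates.

## Worked example

```python
from mcdetect import (PhantomSpec, generate_phantom, MicrocalcificationDetector,
                      Tissue, label_blocks)

image, truth, annotations = generate_phantom(PhantomSpec(tissue="dense", seed=8))
det = MicrocalcificationDetector(tissue=Tissue.DENSE_GLANDULAR, seed=8)
mask = det.fit_predict(image, annotations)
report = label_blocks(mask, annotations, block_px=50)

print(f"K = {det.k_}, NMD = {det.diagnostic_.nmd:.3f}")
print(f"clusters detected: {sum(report.region_hits)}/{len(report.region_hits)}")
print(f"FP blocks = {report.fp}, TN blocks = {report.tn}, "
      f"specificity = {report.specificity:.1f}%")
```

prints

```
K = 0.2, NMD = 0.125
clusters detected: 3/3
FP blocks = 3, TN blocks = 90, specificity = 96.8%
```

K = 0.2 is the dense-tissue operating point; NMD (normalized mean
difference) of 0.125 says the synthetic training lesions sit ≈32 graylevels
above the surrounding breast tissue — enough class separation to find all
three planted clusters while misfiring in only 3 of 93 healthy blocks.

The same pipeline is scriptable from the shell:

```sh
mcdetect phantom --seed 21 --tissue fatty --out-dir work/
mcdetect detect work/phantom.pgm --annotations work/annotations.txt \
         --tissue fatty --seed 3 --out-dir work/det
mcdetect evaluate work/det/mask_filtered.png work/annotations.txt --out-dir work/eval
mcdetect sweep-k work/phantom.pgm --annotations work/annotations.txt \
         -k 0.2 -k 0.5 -k 1.0 --out-dir work/sweep
```

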