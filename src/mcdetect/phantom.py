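"""Synthetic mammogram phantoms with planted ground truth.

The phantom stands in for real screening data in tests and studies: a bright
half-elliptical breast region on a dark film background, filled with
spatially correlated Gaussian texture whose mean and variance depend on the
tissue preset (dense-glandular tissue is brighter and more variable than
fatty), plus planted microcalcification clusters — groups of >= 3 small
bright discs within a 1 cm^2 area — with known locations.  Every phantom
returns the image, a binary truth mask of lesion pixels, and MIAS-style
annotations circumscribing each planted cluster, so the full detection
pipeline can be scored against exact ground truth.

The texture is a correlated Gaussian field — smoothed white noise rescaled
to the preset mean/sd — with a default correlation length of 10 px (2 mm),
the scale of glandular structure.  Keeping the tissue variance at a scale
coarse relative to lesions (0.1-1 mm) matters: a field whose variance lives
at the lesion scale is a breast made of lesion-sized blobs, against which
no detector could work in principle.

Calibration constants (not measurements of real film): fatty preset mean
120 / sd 12, dense preset mean 170 / sd 25, background level 10.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage

from .imagery import BreastAnnotation, Abnormality, GrayImage, Severity, Tissue
from .synthesis import ClusterSpec, gaussian_kernel, make_std_model

__all__ = ["PhantomSpec", "TISSUE_PRESETS", "generate_phantom", "phantom_nmd"]

#: (breast_mean, breast_sd) calibration constants per tissue preset; the
#: dense preset must dominate the fatty one in both mean and variance.
TISSUE_PRESETS = {
    "fatty": (120.0, 12.0),
    "dense": (170.0, 25.0),
}


@dataclass
class PhantomSpec:
    """Parameters of one synthetic mammogram.

    ``tissue`` selects the texture preset ("fatty" or "dense"); explicit
    ``breast_mean``/``breast_sd`` override it.  ``mc_clusters`` gives
    explicit cluster geometry; when None, ``n_clusters`` clusters are placed
    at seeded-random positions inside the breast.  ``mc_contrast`` is the
    additive brightness (graylevels) of planted lesions before edge
    smoothing; the default 70 keeps the normalized mean difference at or
    above 0.1 for either tissue preset (visible but not trivial).
    """

    shape: tuple[int, int] = (512, 512)
    tissue: str = "fatty"
    bg_level: float = 10.0
    breast_mean: Optional[float] = None
    breast_sd: Optional[float] = None
    texture_corr_px: float = 10.0
    mc_clusters: Optional[list[ClusterSpec]] = None
    n_clusters: int = 3
    mc_contrast: float = 70.0
    marker: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tissue not in TISSUE_PRESETS:
            raise ValueError(f"tissue must be one of {sorted(TISSUE_PRESETS)}")
        mean, sd = TISSUE_PRESETS[self.tissue]
        if self.breast_mean is None:
            self.breast_mean = mean
        if self.breast_sd is None:
            self.breast_sd = sd
        if self.breast_mean <= self.bg_level:
            raise ValueError("breast_mean must exceed bg_level")

    @property
    def tissue_enum(self) -> Tissue:
        return Tissue.DENSE_GLANDULAR if self.tissue == "dense" else Tissue.FATTY


def _breast_ellipse(shape: tuple[int, int]) -> np.ndarray:
    """Half-ellipse breast region attached to the left image edge."""
    h, w = shape
    a, b = 0.45 * h, 0.70 * w
    rr, cc = np.mgrid[0:h, 0:w]
    return ((rr - h / 2.0) / a) ** 2 + (cc / b) ** 2 <= 1.0


def _auto_clusters(
    region: np.ndarray, n_clusters: int, rng: np.random.Generator,
    cluster_radius: float = 15.0, n_mcs: int = 6,
    mc_radius_range: tuple[float, float] = (1.0, 2.5),
    min_separation: float = 70.0, max_tries: int = 500,
) -> list[ClusterSpec]:
    margin = int(np.ceil(cluster_radius)) + 5
    interior = ndimage.binary_erosion(region, iterations=margin)
    candidates = np.argwhere(interior)
    centers: list[tuple[int, int]] = []
    for _ in range(max_tries):
        r, c = candidates[rng.integers(len(candidates))]
        if all((r - r0) ** 2 + (c - c0) ** 2 >= min_separation**2 for r0, c0 in centers):
            centers.append((int(r), int(c)))
        if len(centers) == n_clusters:
            break
    if len(centers) < n_clusters:
        raise RuntimeError(f"could not place {n_clusters} separated clusters")
    return [
        ClusterSpec(center=ctr, n_mcs=n_mcs, mc_radius_range=mc_radius_range,
                    cluster_radius_px=cluster_radius)
        for ctr in centers
    ]


def generate_phantom(
    spec: PhantomSpec,
) -> tuple[GrayImage, np.ndarray, list[BreastAnnotation]]:
    """Render a phantom; deterministic (bit-exact) for a fixed spec.

    Returns ``(image, truth_mask, truth_annotations)`` where ``truth_mask``
    marks planted lesion pixels and each annotation circle circumscribes one
    planted cluster.  Raises if a requested cluster center falls outside the
    breast region.
    """
    h, w = spec.shape
    ss = np.random.SeedSequence(spec.seed)
    rng_texture, rng_place, rng_model = [np.random.default_rng(s) for s in ss.spawn(3)]

    region = _breast_ellipse(spec.shape)

    # glandular-scale correlated texture: smoothed white noise rescaled
    noise = ndimage.gaussian_filter(rng_texture.standard_normal((h, w)), spec.texture_corr_px)
    inside = noise[region]
    noise = (noise - inside.mean()) / inside.std()
    img = np.where(region, spec.breast_mean + spec.breast_sd * noise, 0.0)
    img[~region] = spec.bg_level + rng_texture.normal(0.0, 2.0, size=(h, w))[~region]

    if spec.marker:
        img[10:40, w - 70 : w - 20] = 230.0

    clusters = spec.mc_clusters
    if clusters is None and spec.n_clusters > 0:
        clusters = _auto_clusters(region, spec.n_clusters, rng_place)
    clusters = clusters or []
    for cl in clusters:
        if not region[cl.center]:
            raise ValueError(f"cluster center {cl.center} lies outside the breast region")

    model_seed = int(rng_model.integers(0, 2**31 - 1))
    truth = make_std_model(spec.shape, clusters, seed=model_seed)

    # additive lesions with soft edges
    img = img + ndimage.convolve(spec.mc_contrast * truth.astype(np.float64),
                                 gaussian_kernel(3, 0.8), mode="nearest")
    img = np.clip(img, 0.0, 255.0)

    annotations = []
    for i, cl in enumerate(clusters):
        annotations.append(
            BreastAnnotation(
                ref_id=f"phantom{i:02d}",
                tissue=spec.tissue_enum,
                abnormality=Abnormality.CALC,
                severity=Severity.BENIGN,
                center_row=cl.center[0],
                center_col=cl.center[1],
                radius_px=cl.cluster_radius_px + cl.mc_radius_range[1] + 2.0,
            )
        )
    return GrayImage(img), truth, annotations


def phantom_nmd(image: GrayImage, truth_mask: np.ndarray, breast_region: np.ndarray,
                scale: float = 255.0) -> float:
    """Normalized mean difference of planted lesions against breast tissue."""
    truth_mask = np.asarray(truth_mask).astype(bool)
    breast_region = np.asarray(breast_region).astype(bool)
    if not truth_mask.any() or not breast_region.any():
        raise ValueError("truth_mask and breast_region must be nonempty")
    return (
        float(image.pixels[truth_mask].mean()) - float(image.pixels[breast_region].mean())
    ) / scale
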