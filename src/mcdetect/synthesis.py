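"""Synthetic microcalcification construction and blending.

The self-learning classifier needs training pixels for the lesion class but
no labeled lesions exist in the input image.  This module builds a *standard
model* — a binary mask of synthetic microcalcifications (small filled discs,
0.2–1 mm at 200 um/pixel, grouped in clusters of three or more) — and blends
it into the mammogram: each synthetic pixel receives an additive boost equal
to a fraction K of the local tissue graylevel, smoothed by a small lowpass
kernel H so the planted spots have soft edges like real calcifications.

K (the modeling constant) controls how bright the synthetic lesions are
relative to their surroundings; small K suits dense-glandular tissue where
real lesions have low contrast, larger K suits fatty tissue.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .imagery import GrayImage, Tissue

__all__ = [
    "ClusterSpec",
    "MCModel",
    "HybridImage",
    "GenerationError",
    "gaussian_kernel",
    "make_std_model",
    "blend",
    "choose_k",
]


class GenerationError(RuntimeError):
    """Raised when a cluster cannot be realized without overlap."""


@dataclass
class ClusterSpec:
    """Geometry of one synthetic microcalcification cluster.

    ``n_mcs`` filled discs with radii drawn uniformly from
    ``mc_radius_range`` (pixels) are placed at random offsets within
    ``cluster_radius_px`` of ``center``.  A cluster must fit inside one
    1 cm^2 evaluation block, hence ``cluster_radius_px <= 25`` at the
    default 200 um pitch.
    """

    center: tuple[int, int]
    n_mcs: int = 4
    mc_radius_range: tuple[float, float] = (1.0, 3.0)
    cluster_radius_px: float = 20.0

    def __post_init__(self) -> None:
        if self.n_mcs < 3:
            raise ValueError("a cluster needs at least 3 microcalcifications")
        lo, hi = self.mc_radius_range
        if not (1.0 <= lo <= hi <= 3.0):
            raise ValueError("mc_radius_range must lie within [1, 3] pixels")
        if self.cluster_radius_px > 25:
            raise ValueError("cluster_radius_px must be <= 25 (cluster must fit a 50x50 block)")
        if self.cluster_radius_px <= 0:
            raise ValueError("cluster_radius_px must be positive")


def gaussian_kernel(size: int = 3, sigma: float = 0.8) -> np.ndarray:
    """Normalized 2-D Gaussian lowpass kernel (default 3x3, sigma 0.8)."""
    if size < 1 or size % 2 == 0:
        raise ValueError("kernel size must be odd and >= 1")
    ax = np.arange(size) - size // 2
    g = np.exp(-(ax[:, None] ** 2 + ax[None, :] ** 2) / (2.0 * sigma**2))
    return g / g.sum()


@dataclass
class MCModel:
    """Binary standard model plus blending parameters.

    ``std_model`` marks the synthetic lesion pixels, ``K`` in (0, 1] scales
    their brightness relative to the underlying tissue, and ``H`` is the
    unit-sum lowpass kernel used to soften lesion edges.  K = 0 is tolerated
    (it makes blending the identity, useful for testing) but, like any value
    outside the typical [0.1, 1] range, triggers a warning.
    """

    std_model: np.ndarray
    K: float
    H: np.ndarray = field(default_factory=gaussian_kernel)

    def __post_init__(self) -> None:
        self.std_model = np.asarray(self.std_model)
        if not np.isin(self.std_model, (0, 1)).all():
            raise ValueError("std_model must be binary")
        self.std_model = self.std_model.astype(np.uint8)
        if self.K < 0 or self.K > 1:
            raise ValueError(f"modeling constant K={self.K} outside [0, 1]")
        if not 0.1 <= self.K <= 1.0:
            warnings.warn(
                f"K={self.K} is outside the typical range [0.1, 1]", stacklevel=2
            )
        self.H = np.asarray(self.H, dtype=np.float64)
        if self.H.ndim != 2 or (self.H < 0).any():
            raise ValueError("H must be a nonnegative 2-D kernel")
        s = self.H.sum()
        if s <= 0:
            raise ValueError("H must have positive sum")
        self.H = self.H / s


@dataclass
class HybridImage:
    """A mammogram with synthetic microcalcifications blended in."""

    pixels: GrayImage
    synthetic_coords: np.ndarray  # (n, 2) array of (row, col)


def make_std_model(
    shape: tuple[int, int],
    clusters: Sequence[ClusterSpec],
    seed: int,
    max_tries: int = 200,
) -> np.ndarray:
    """Build the binary standard model: disjoint filled discs per cluster.

    Deterministic for a fixed ``(shape, clusters, seed)``.  Raises
    :class:`GenerationError` if a cluster cannot place its discs without
    overlap within ``max_tries`` rejection-sampling rounds, or if the total
    synthetic area would exceed 1% of the image (the working assumption is
    that lesions occupy no more than 1% of a mammogram).
    """
    h, w = shape
    rng = np.random.default_rng(seed)
    mask = np.zeros((h, w), dtype=np.uint8)
    rr, cc = np.mgrid[0:h, 0:w]

    placed: list[tuple[float, float, float]] = []  # (row, col, radius) of all discs
    for spec in clusters:
        cr, ccol = spec.center
        lo, hi = spec.mc_radius_range
        for _ in range(max_tries):
            # sample all discs of this cluster, then accept iff pairwise disjoint
            radii = rng.uniform(lo, hi, size=spec.n_mcs)
            ang = rng.uniform(0, 2 * np.pi, size=spec.n_mcs)
            # sqrt for uniform density over the cluster disc
            dist = spec.cluster_radius_px * np.sqrt(rng.uniform(0, 1, size=spec.n_mcs))
            rows = cr + dist * np.sin(ang)
            cols = ccol + dist * np.cos(ang)
            cand = list(zip(rows, cols, radii))
            # a 1-px guard gap keeps discs 8-disconnected after rasterization
            if _all_disjoint(cand + placed, gap=1.5):
                break
        else:
            raise GenerationError(
                f"could not place {spec.n_mcs} disjoint discs within "
                f"radius {spec.cluster_radius_px} of {spec.center} "
                f"after {max_tries} tries"
            )
        placed.extend(cand)
        for r0, c0, rad in cand:
            mask[(rr - r0) ** 2 + (cc - c0) ** 2 <= rad**2] = 1

    if mask.sum() > 0.01 * h * w:
        raise GenerationError("synthetic pixels exceed 1% of the image area")
    return mask


def _all_disjoint(discs: Sequence[tuple[float, float, float]], gap: float) -> bool:
    for i in range(len(discs)):
        r0, c0, a = discs[i]
        for j in range(i + 1, len(discs)):
            r1, c1, b = discs[j]
            if (r0 - r1) ** 2 + (c0 - c1) ** 2 < (a + b + gap) ** 2:
                return False
    return True


def blend(image: GrayImage, model: MCModel) -> HybridImage:
    """Blend the standard model into the mammogram.

    The synthetic layer L = K * I * M (each lesion pixel gets a fraction K of
    its underlying graylevel) is smoothed with the lowpass kernel H and added
    to the image, then the result is clipped to [0, 255].  Smoothing acts on
    the synthetic layer only, so pixels outside the model support dilated by
    H's footprint are bit-identical to the input, and the K -> 0 limit
    returns the input exactly.
    """
    m = model.std_model
    if m.shape != image.shape:
        raise ValueError(f"shape mismatch: model {m.shape} vs image {image.shape}")
    if model.K < 0:
        raise ValueError("K must be non-negative")

    layer = model.K * image.pixels * m
    smoothed_layer = ndimage.convolve(layer, model.H, mode="nearest")
    # confine the smoothed boost to the model support dilated by H's footprint
    support = ndimage.binary_dilation(m.astype(bool), structure=model.H > 0)
    out = image.pixels + np.where(support, smoothed_layer, 0.0)
    out = np.clip(out, 0.0, 255.0)
    coords = np.argwhere(m == 1)
    return HybridImage(GrayImage(out, image.pixel_pitch_um), coords)


#: default modeling constants per tissue regime (inside the suitable ranges
#: 0.1–0.4 for dense-glandular, 0.5–1 for fatty; 0.2 is the best operating
#: point of the reference K sweep).
K_DENSE = 0.2
K_FATTY = 0.5

#: breast-region intensity variance above which the dense rule applies.
DEFAULT_VARIANCE_THRESHOLD = 400.0


def choose_k(
    image: GrayImage,
    breast_mask: np.ndarray,
    tissue_hint: Optional[Tissue] = None,
    variance_threshold: float = DEFAULT_VARIANCE_THRESHOLD,
) -> float:
    """Pick the modeling constant K from tissue type or breast statistics.

    Dense-glandular tissue (high mean/variance, low lesion contrast) gets
    K = 0.2; fatty and fatty-glandular tissue gets K = 0.5.  Without a hint
    the breast-region intensity variance decides: above
    ``variance_threshold`` the dense rule applies.
    """
    breast_mask = np.asarray(breast_mask, dtype=bool)
    if not breast_mask.any():
        raise ValueError("breast_mask is empty")
    if tissue_hint is not None:
        return K_DENSE if tissue_hint is Tissue.DENSE_GLANDULAR else K_FATTY
    var = float(np.var(image.pixels[breast_mask]))
    return K_DENSE if var > variance_threshold else K_FATTY
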