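"""Post-processing: breast masking and the cluster physiology rule.

The raw pixel classification produces false detections concentrated outside
the breast (dark background, film border, radiographic markers).  Otsu's
threshold on the original graylevel image separates the bright breast from
the dark surround; detections outside the resulting breast mask are vetoed.
A second, physiological rule exploits the fact that clinically relevant
microcalcifications occur in clusters of three or more within a 1 cm^2 area
(a 50x50-pixel block at 200 um/pixel): detected components whose block holds
fewer than ``min_count`` component centroids are discarded.
"""

from __future__ import annotations

from collections import Counter

import numpy as np
from scipy import ndimage

from .classifier import DetectionMask
from .imagery import GrayImage

__all__ = [
    "otsu_threshold",
    "breast_mask",
    "apply_physiology_filter",
    "cm_to_pixels",
    "component_centroids",
]

EIGHT_CONN = np.ones((3, 3), dtype=bool)


def otsu_threshold(image: GrayImage) -> int:
    """Otsu's threshold on the 8-bit histogram.

    Evaluates every candidate threshold t in 0..255 (foreground = values
    strictly above t) and returns the t maximizing the between-class
    variance w0*w1*(mu0-mu1)^2; ties resolve to the smallest t.  Raises on
    constant images, where no threshold separates anything.
    """
    vals = np.clip(np.rint(image.pixels), 0, 255).astype(np.int64)
    hist = np.bincount(vals.ravel(), minlength=256).astype(np.float64)
    if np.count_nonzero(hist) < 2:
        raise ValueError("image has fewer than 2 distinct values")
    total = hist.sum()
    p = hist / total
    levels = np.arange(256, dtype=np.float64)
    omega0 = np.cumsum(p)                     # weight of class <= t
    mu_cum = np.cumsum(p * levels)
    mu_total = mu_cum[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = mu_cum / omega0
        mu1 = (mu_total - mu_cum) / (1.0 - omega0)
        sigma_b = omega0 * (1.0 - omega0) * (mu0 - mu1) ** 2
    sigma_b = np.nan_to_num(sigma_b, nan=-np.inf)
    return int(np.argmax(sigma_b))  # argmax returns the first (smallest) maximizer


def breast_mask(image: GrayImage) -> np.ndarray:
    """Segment the breast: Otsu foreground, largest component, holes filled."""
    t = otsu_threshold(image)
    fg = image.pixels > t
    labeled, n = ndimage.label(fg, structure=EIGHT_CONN)
    if n == 0:
        return fg
    sizes = ndimage.sum_labels(np.ones_like(labeled), labeled, index=np.arange(1, n + 1))
    largest = int(np.argmax(sizes)) + 1
    mask = labeled == largest
    return ndimage.binary_fill_holes(mask)


def component_centroids(mask: np.ndarray) -> np.ndarray:
    """Centroids (n, 2) of the 8-connected components of a binary mask."""
    labeled, n = ndimage.label(np.asarray(mask).astype(bool), structure=EIGHT_CONN)
    if n == 0:
        return np.empty((0, 2))
    return np.asarray(ndimage.center_of_mass(mask, labeled, index=np.arange(1, n + 1)))


def apply_physiology_filter(
    mask: DetectionMask,
    breast: np.ndarray,
    block_px: int,
    min_count: int = 3,
) -> DetectionMask:
    """Keep only detections that form plausible clusters inside the breast.

    Detections outside the breast mask are zeroed; the survivors' 8-connected
    components are kept iff the non-overlapping ``block_px`` x ``block_px``
    tile containing the component centroid holds at least ``min_count``
    component centroids.  The filter is idempotent and never adds detections.
    """
    if block_px < 1:
        raise ValueError("block_px must be >= 1")
    inside = mask.labels.astype(bool) & np.asarray(breast).astype(bool)
    labeled, n = ndimage.label(inside, structure=EIGHT_CONN)
    if n == 0:
        return DetectionMask(np.zeros_like(mask.labels))
    centroids = np.asarray(
        ndimage.center_of_mass(inside, labeled, index=np.arange(1, n + 1))
    )
    blocks = (centroids // block_px).astype(int)
    counts = Counter(map(tuple, blocks))
    keep = np.array([counts[tuple(b)] >= min_count for b in blocks])
    keep_labels = np.flatnonzero(keep) + 1
    out = np.isin(labeled, keep_labels)
    return DetectionMask(out.astype(np.uint8))


def cm_to_pixels(length_cm: float, pixel_pitch_um: float) -> int:
    """Physical length to pixels: round(cm * 10000 / pitch_um)."""
    if length_cm <= 0 or pixel_pitch_um <= 0:
        raise ValueError("length and pitch must be positive")
    return int(round(length_cm * 10000.0 / pixel_pitch_um))


def component_table(mask: DetectionMask, block_px: int = 50):
    """Tabulate detection components: id, centroid, area, block index."""
    import pandas as pd

    labeled, n = ndimage.label(mask.labels.astype(bool), structure=EIGHT_CONN)
    rows = []
    for i in range(1, n + 1):
        r, c = ndimage.center_of_mass(mask.labels, labeled, index=i)
        rows.append({
            "component": i,
            "centroid_row": r,
            "centroid_col": c,
            "area_px": int((labeled == i).sum()),
            "block_row": int(r // block_px),
            "block_col": int(c // block_px),
        })
    return pd.DataFrame(rows, columns=["component", "centroid_row", "centroid_col",
                                       "area_px", "block_row", "block_col"])
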