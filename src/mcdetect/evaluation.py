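"""Block-based evaluation of a detection mask against annotations.

The image is tiled into non-overlapping ``block_px`` x ``block_px`` blocks
(residual rows/columns are dropped).  Blocks intersecting an annotated real
lesion circle are excluded from the healthy census; each annotated region
scores a true positive when at least one detected component centroid falls
inside its circle and a false negative otherwise.  A remaining healthy block
is a false positive when it contains ``fp_min_count`` or more detected
component centroids (three, matching the clinical cluster definition of >= 3
calcifications per 1 cm^2), else a true negative.  Summary metrics are

    sensitivity = 100 * TP / (TP + FN),   specificity = 100 * TN / (TN + FP).

A comparison variant uses 87x87 blocks and counts a false positive as soon
as a single component is detected in a healthy block.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .classifier import DetectionMask
from .imagery import BreastAnnotation
from .postprocess import component_centroids

__all__ = [
    "BlockReport",
    "label_blocks",
    "metrics",
    "fp_per_image",
    "evaluate_variant_87",
]


@dataclass
class BlockReport:
    """Outcome of block labeling for one image.

    ``block_labels`` maps the tiling grid to one of {"FP", "TN", "excluded"};
    TP/FN are per annotated region, not per block.  ``sensitivity`` and
    ``specificity`` are percentages, or None when their denominator is zero
    (e.g. no annotated regions).
    """

    block_px: int
    fp_min_count: int
    tp: int
    fn: int
    fp: int
    tn: int
    excluded: int
    block_labels: np.ndarray = field(repr=False)
    region_hits: list[bool] = field(default_factory=list, repr=False)

    @property
    def sensitivity(self) -> Optional[float]:
        s, _ = metrics(self.tp, self.fn, self.tn, self.fp)
        return s

    @property
    def specificity(self) -> Optional[float]:
        _, sp = metrics(self.tp, self.fn, self.tn, self.fp)
        return sp

    @property
    def total_blocks(self) -> int:
        return self.block_labels.size

    def to_dict(self) -> dict:
        return {
            "block_px": self.block_px,
            "fp_min_count": self.fp_min_count,
            "TP": self.tp,
            "FN": self.fn,
            "FP": self.fp,
            "TN": self.tn,
            "excluded": self.excluded,
            "sensitivity_pct": self.sensitivity,
            "specificity_pct": self.specificity,
        }

    def to_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    def to_frame(self) -> pd.DataFrame:
        """Per-block rows: block_row, block_col, label."""
        rows = [
            {"block_row": i, "block_col": j, "label": self.block_labels[i, j]}
            for i in range(self.block_labels.shape[0])
            for j in range(self.block_labels.shape[1])
        ]
        return pd.DataFrame(rows)


def metrics(tp: int, fn: int, tn: int, fp: int) -> tuple[Optional[float], Optional[float]]:
    """Sensitivity and specificity as percentages; None when undefined."""
    for v in (tp, fn, tn, fp):
        if v < 0:
            raise ValueError("counts must be non-negative")
    sens = 100.0 * tp / (tp + fn) if (tp + fn) > 0 else None
    spec = 100.0 * tn / (tn + fp) if (tn + fp) > 0 else None
    return sens, spec


def label_blocks(
    mask: DetectionMask,
    annotations: Sequence[BreastAnnotation] = (),
    block_px: int = 50,
    fp_min_count: int = 3,
    breast: Optional[np.ndarray] = None,
) -> BlockReport:
    """Tile the mask and label blocks/regions; see the module docstring.

    If ``breast`` is given, blocks lying entirely outside the breast mask are
    additionally excluded from the FP/TN census (by default all non-annotated
    tiles are counted).
    """
    h, w = mask.shape
    if block_px > min(h, w):
        raise ValueError(f"block_px={block_px} exceeds image size {mask.shape}")
    nbr, nbc = h // block_px, w // block_px

    centroids = component_centroids(mask.labels)

    located = [a for a in annotations if a.has_location]
    region_hits: list[bool] = []
    for a in located:
        d2 = (centroids[:, 0] - a.center_row) ** 2 + (centroids[:, 1] - a.center_col) ** 2
        region_hits.append(bool(len(centroids) and (d2 <= a.radius_px**2).any()))
    tp = int(sum(region_hits))
    fn = len(located) - tp

    # centroid count per tile (centroids in residual margins fall outside)
    counts = np.zeros((nbr, nbc), dtype=int)
    for r, c in centroids:
        br, bc = int(r // block_px), int(c // block_px)
        if 0 <= br < nbr and 0 <= bc < nbc:
            counts[br, bc] += 1

    labels = np.full((nbr, nbc), "TN", dtype=object)
    for i in range(nbr):
        for j in range(nbc):
            r0, c0 = i * block_px, j * block_px
            if any(
                _block_circle_intersect(r0, c0, block_px, a.center_row, a.center_col, a.radius_px)
                for a in located
            ):
                labels[i, j] = "excluded"
            elif breast is not None and not breast[r0 : r0 + block_px, c0 : c0 + block_px].any():
                labels[i, j] = "excluded"
            elif counts[i, j] >= fp_min_count:
                labels[i, j] = "FP"

    fp = int((labels == "FP").sum())
    tn = int((labels == "TN").sum())
    excluded = int((labels == "excluded").sum())
    return BlockReport(
        block_px=block_px,
        fp_min_count=fp_min_count,
        tp=tp,
        fn=fn,
        fp=fp,
        tn=tn,
        excluded=excluded,
        block_labels=labels,
        region_hits=region_hits,
    )


def _block_circle_intersect(r0: int, c0: int, side: int, cr: float, cc: float, rad: float) -> bool:
    nr = min(max(cr, r0), r0 + side - 1)
    nc = min(max(cc, c0), c0 + side - 1)
    return (nr - cr) ** 2 + (nc - cc) ** 2 <= rad**2


def fp_per_image(reports: Sequence[BlockReport]) -> float:
    """Mean false-positive block count over a set of per-image reports."""
    if not reports:
        raise ValueError("need at least one report")
    return float(np.mean([r.fp for r in reports]))


def evaluate_variant_87(
    mask: DetectionMask,
    annotations: Sequence[BreastAnnotation] = (),
    breast: Optional[np.ndarray] = None,
) -> BlockReport:
    """Comparison protocol: 87x87 blocks, one detected component marks a FP."""
    return label_blocks(mask, annotations, block_px=87, fp_min_count=1, breast=breast)
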