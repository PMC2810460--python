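"""Self-learning Gaussian Bayes pixel classification.

Two classes are modeled: lesion (microcalcification, label 1) and healthy
tissue (label 0).  Each class is a 4-D Gaussian with mean m_j and covariance
C_j estimated from training pixels drawn from the input image itself: the
lesion class from the synthetic standard-model pixels of the hybrid image,
the healthy class from two randomly placed background ROIs.  With equal
priors the per-class score is the log-posterior up to a shared constant,

    d_j(x) = -1/2 ln|C_j| - 1/2 (x - m_j)^T C_j^{-1} (x - m_j),

and a pixel is labeled lesion iff d_lesion(x) strictly exceeds d_healthy(x)
(ties go to healthy: a detection requires strict evidence).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .features import CHANNEL_NAMES, FeatureStack
from .imagery import GrayImage

__all__ = [
    "ClassParams",
    "TrainingSets",
    "DetectionMask",
    "MeanDifferenceDiagnostic",
    "DegenerateFeatureError",
    "GaussianBayesClassifier",
    "select_training_samples",
    "estimate_params",
    "decision_value",
    "decision_values",
    "classify",
    "mean_difference_diagnostic",
]

#: ridge scale for near-singular covariances, relative to trace/dim.
RIDGE_EPS = 1e-6

#: healthy-class training-sample budget (split over two ROIs).
DEFAULT_BG_TOTAL = 4300

#: required healthy:lesion training-set size ratio.
MIN_BG_RATIO = 3.0


class DegenerateFeatureError(ValueError):
    """Raised when a training set has zero variance in some channel."""


@dataclass
class ClassParams:
    """Gaussian parameters of one class: mean, covariance and caches."""

    mean: np.ndarray
    cov: np.ndarray
    log_det: float
    inv_cov: np.ndarray
    n_samples: int

    @classmethod
    def from_samples(cls, X: np.ndarray) -> "ClassParams":
        """Estimate from an (n, d) sample matrix; see :func:`estimate_params`."""
        X = np.asarray(X, dtype=np.float64)
        n, d = X.shape
        if n < max(5, d + 1):
            raise ValueError(f"need at least {max(5, d + 1)} samples, got {n}")
        mean = X.mean(axis=0)
        cov = np.cov(X, rowvar=False, ddof=1)
        cov = np.atleast_2d(cov)
        diag = np.diag(cov)
        if np.any(diag == 0.0):
            ch = int(np.argmin(diag))
            name = CHANNEL_NAMES[ch] if ch < len(CHANNEL_NAMES) else str(ch)
            raise DegenerateFeatureError(
                f"channel {ch} ({name}) has zero variance in the training set"
            )
        # ridge against near-singularity (flat ROIs make this a real case)
        ridge = RIDGE_EPS * np.trace(cov) / d
        eigvals = np.linalg.eigvalsh(cov)
        if eigvals.min() < ridge:
            cov = cov + ridge * np.eye(d)
        sign, log_det = np.linalg.slogdet(cov)
        if sign <= 0 or not np.isfinite(log_det):
            raise ValueError("covariance is not positive definite after regularization")
        return cls(mean=mean, cov=cov, log_det=float(log_det),
                   inv_cov=np.linalg.inv(cov), n_samples=n)

    def to_dict(self) -> dict:
        return {
            "mean": self.mean.tolist(),
            "cov": self.cov.tolist(),
            "n_samples": int(self.n_samples),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ClassParams":
        cov = np.asarray(d["cov"], dtype=np.float64)
        sign, log_det = np.linalg.slogdet(cov)
        return cls(
            mean=np.asarray(d["mean"], dtype=np.float64),
            cov=cov,
            log_det=float(log_det),
            inv_cov=np.linalg.inv(cov),
            n_samples=int(d["n_samples"]),
        )


@dataclass
class TrainingSets:
    """Pixel coordinates of the two training sets plus the background ROIs.

    ``bg_roi_boxes`` holds two ``(row0, col0, side)`` squares; the healthy
    set must be at least three times the lesion set.
    """

    mc_coords: np.ndarray
    bg_coords: np.ndarray
    bg_roi_boxes: list[tuple[int, int, int]]

    def __post_init__(self) -> None:
        if len(self.bg_roi_boxes) != 2:
            raise ValueError("exactly two background ROIs are required")
        if len(self.bg_coords) < MIN_BG_RATIO * len(self.mc_coords):
            raise ValueError(
                f"healthy training set ({len(self.bg_coords)}) must be at least "
                f"{MIN_BG_RATIO}x the lesion set ({len(self.mc_coords)})"
            )
        mc = {tuple(c) for c in np.asarray(self.mc_coords)}
        bg = {tuple(c) for c in np.asarray(self.bg_coords)}
        if mc & bg:
            raise ValueError("lesion and healthy training sets overlap")


@dataclass
class DetectionMask:
    """Binary label raster: 1 = microcalcification, 0 = healthy."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary")
        self.labels = self.labels.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape


def select_training_samples(
    model_mask: np.ndarray,
    image_shape: tuple[int, int],
    bg_total: int = DEFAULT_BG_TOTAL,
    seed: int = 0,
    exclusion: Optional[Sequence[tuple[int, int, float]]] = None,
    within: Optional[np.ndarray] = None,
    max_tries: int = 500,
) -> TrainingSets:
    """Pick the lesion and healthy training pixels from one image.

    Lesion coordinates are all standard-model pixels.  Healthy coordinates
    fill two square ROIs of side ceil(sqrt(bg_total/2)) placed uniformly at
    random (seeded), mutually disjoint and avoiding the dilated model mask
    and any ``exclusion`` circles ``(row, col, radius)`` — e.g. annotated
    real lesions.  If ``within`` is given, ROIs must lie entirely inside it
    (typically the breast mask).
    """
    model_mask = np.asarray(model_mask).astype(bool)
    if not model_mask.any():
        raise ValueError("model_mask is empty")
    h, w = image_shape
    mc_coords = np.argwhere(model_mask)
    side = int(np.ceil(np.sqrt(bg_total / 2.0)))
    if 2 * side * side < MIN_BG_RATIO * len(mc_coords):
        raise ValueError(
            f"bg_total={bg_total} gives {2 * side * side} healthy samples, "
            f"fewer than {MIN_BG_RATIO}x the {len(mc_coords)} lesion samples"
        )
    if side > h or side > w:
        raise ValueError("background ROI does not fit in the image")

    # keep-out: model support dilated one kernel footprint
    keepout = ndimage.binary_dilation(model_mask, structure=np.ones((3, 3)), iterations=2)
    rng = np.random.default_rng(seed)
    boxes: list[tuple[int, int, int]] = []
    for _ in range(max_tries):
        r0 = int(rng.integers(0, h - side + 1))
        c0 = int(rng.integers(0, w - side + 1))
        if keepout[r0 : r0 + side, c0 : c0 + side].any():
            continue
        if within is not None and not within[r0 : r0 + side, c0 : c0 + side].all():
            continue
        if exclusion and any(
            _box_circle_intersect(r0, c0, side, er, ec, rad) for er, ec, rad in exclusion
        ):
            continue
        if any(_boxes_overlap(r0, c0, side, *b) for b in boxes):
            continue
        boxes.append((r0, c0, side))
        if len(boxes) == 2:
            break
    if len(boxes) < 2:
        raise RuntimeError(
            f"could not place 2 disjoint background ROIs after {max_tries} tries"
        )
    bg_coords = np.concatenate(
        [
            np.stack(
                np.meshgrid(np.arange(r0, r0 + s), np.arange(c0, c0 + s), indexing="ij"),
                axis=-1,
            ).reshape(-1, 2)
            for r0, c0, s in boxes
        ]
    )
    return TrainingSets(mc_coords=mc_coords, bg_coords=bg_coords, bg_roi_boxes=boxes)


def _boxes_overlap(r0, c0, s0, r1, c1, s1) -> bool:
    return not (r0 + s0 <= r1 or r1 + s1 <= r0 or c0 + s0 <= c1 or c1 + s1 <= c0)


def _box_circle_intersect(r0, c0, side, cr, cc, rad) -> bool:
    nr = min(max(cr, r0), r0 + side - 1)
    nc = min(max(cc, c0), c0 + side - 1)
    return (nr - cr) ** 2 + (nc - cc) ** 2 <= rad**2


def estimate_params(features: FeatureStack, coords: np.ndarray) -> ClassParams:
    """Sample mean and unbiased covariance of the feature vectors at coords."""
    return ClassParams.from_samples(features.vectors_at(np.asarray(coords)))


def decision_value(x: np.ndarray, params: ClassParams) -> float:
    """Per-class score d_j(x) = -1/2 ln|C_j| - 1/2 Mahalanobis^2(x; m_j, C_j)."""
    x = np.asarray(x, dtype=np.float64)
    if not np.all(np.isfinite(x)):
        raise ValueError("feature vector contains non-finite values")
    diff = x - params.mean
    return float(-0.5 * params.log_det - 0.5 * diff @ params.inv_cov @ diff)


def decision_values(X: np.ndarray, params: ClassParams) -> np.ndarray:
    """Vectorized :func:`decision_value` over an (n, d) matrix."""
    diff = np.asarray(X, dtype=np.float64) - params.mean
    maha = np.einsum("ij,jk,ik->i", diff, params.inv_cov, diff)
    return -0.5 * params.log_det - 0.5 * maha


def classify(features: FeatureStack, mc: ClassParams, bg: ClassParams) -> DetectionMask:
    """Label each pixel 1 iff the lesion score strictly beats the healthy one."""
    X = features.as_matrix()
    labels = decision_values(X, mc) > decision_values(X, bg)
    return DetectionMask(labels.reshape(features.shape).astype(np.uint8))


@dataclass
class MeanDifferenceDiagnostic:
    """Interclass separation summary used to vet the modeling constant K.

    ``nmd`` is the normalized mean difference: (mean graylevel over the
    synthetic lesion pixels - mean graylevel over the breast region) / 255.
    Very large per-channel mean differences indicate K is too aggressive
    (the classifier latches onto the synthetic tone); very small ones mean
    weak class separation and many false detections.
    """

    mean_difference: np.ndarray
    variance_ratio: np.ndarray
    nmd: float

    def to_dict(self) -> dict:
        return {
            "mean_difference": self.mean_difference.tolist(),
            "variance_ratio": self.variance_ratio.tolist(),
            "nmd": float(self.nmd),
            "channels": list(CHANNEL_NAMES),
        }


#: normalizer for the NMD statistic (full 8-bit range).
NMD_SCALE = 255.0


def mean_difference_diagnostic(
    mc: ClassParams,
    bg: ClassParams,
    image: GrayImage,
    breast_mask: np.ndarray,
    model_mask: np.ndarray,
    nmd_scale: float = NMD_SCALE,
) -> MeanDifferenceDiagnostic:
    """Per-channel mean differences, variance ratios and the NMD."""
    breast_mask = np.asarray(breast_mask).astype(bool)
    model_mask = np.asarray(model_mask).astype(bool)
    if not breast_mask.any() or not model_mask.any():
        raise ValueError("breast_mask and model_mask must be nonempty")
    nmd = (
        float(image.pixels[model_mask].mean()) - float(image.pixels[breast_mask].mean())
    ) / nmd_scale
    return MeanDifferenceDiagnostic(
        mean_difference=mc.mean - bg.mean,
        variance_ratio=np.diag(mc.cov) / np.diag(bg.cov),
        nmd=nmd,
    )


class GaussianBayesClassifier(BaseEstimator, ClassifierMixin):
    """Two-class Gaussian Bayes classifier with equal priors.

    A thin sklearn-style estimator over :class:`ClassParams`: ``fit`` takes
    a design matrix X (n_samples, n_features) and binary labels y, and
    ``predict`` applies the strict-inequality rule (ties -> 0, the healthy
    class).  ``decision_function`` returns d_1(x) - d_0(x).

    Attributes
    ----------
    classes_ : ndarray of shape (2,)
    params_ : dict mapping class label -> :class:`ClassParams`
    """

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("exactly two classes are required")
        self.params_ = {c: ClassParams.from_samples(X[y == c]) for c in self.classes_}
        self.n_features_in_ = X.shape[1]
        return self

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "params_")
        X = np.asarray(X, dtype=np.float64)
        c0, c1 = self.classes_
        return decision_values(X, self.params_[c1]) - decision_values(X, self.params_[c0])

    def predict(self, X) -> np.ndarray:
        c0, c1 = self.classes_
        return np.where(self.decision_function(X) > 0, c1, c0)
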