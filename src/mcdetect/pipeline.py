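"""End-to-end detection pipeline as an sklearn-style estimator.

The flow (self-learning segmentation):

1. mask the breast via Otsu's threshold on the input graylevels;
2. pick the modeling constant K (tissue hint or breast statistics);
3. plant a synthetic standard model of microcalcification clusters inside
   the breast and blend it into the image (hybrid image);
4. extract the 4-channel feature stack from the hybrid image;
5. train the two-class Gaussian Bayes classifier on the synthetic lesion
   pixels vs. two random background ROIs;
6. classify every pixel, erase the known synthetic plants from the result,
   and apply the breast-mask veto plus the >= 3-per-block cluster rule.

``MicrocalcificationDetector`` carries all tunables as constructor
parameters (sklearn conventions: ``get_params``/``set_params``, fitted
attributes with trailing underscores); :func:`detect` and
:func:`run_phantom_study` are thin functional wrappers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .classifier import (
    DetectionMask,
    classify,
    estimate_params,
    mean_difference_diagnostic,
    select_training_samples,
)
from .evaluation import BlockReport, evaluate_variant_87, fp_per_image, label_blocks
from .features import WaveletSpec, stack_features
from .imagery import BreastAnnotation, GrayImage, Tissue
from .phantom import PhantomSpec, generate_phantom, phantom_nmd
from .postprocess import apply_physiology_filter, breast_mask
from .synthesis import ClusterSpec, MCModel, blend, choose_k, gaussian_kernel, make_std_model

__all__ = ["MicrocalcificationDetector", "detect", "run_phantom_study", "StudyResult"]


class MicrocalcificationDetector(BaseEstimator):
    """Self-learning Gaussian Bayes microcalcification detector.

    Parameters
    ----------
    k : float or None
        Modeling constant in (0, 1]; None selects it from ``tissue`` or the
        breast-region variance.
    tissue : Tissue or None
        Tissue hint for K selection (dense-glandular -> 0.2, fatty -> 0.5).
    n_synth_clusters, synth_mcs_per_cluster, synth_mc_radius_range,
    synth_cluster_radius :
        Geometry of the planted standard model used for training.
    bg_total : int
        Healthy-class training budget, split over two random ROIs.
    window, wavelet, levels, extension :
        Feature-extraction settings (local-rank window; wavelet family,
        depth and boundary mode of the highpass channel).
    block_px, min_count :
        Cluster physiology rule: a surviving detection needs ``min_count``
        component centroids in its ``block_px`` x ``block_px`` tile
        (50 px = 1 cm at 200 um/pixel).
    smoothing_sigma : float
        Sigma of the 3x3 Gaussian blend kernel H.
    border_margin_px : int
        Detected components touching this margin just inside the breast
        outline are suppressed as border artifacts (the breast-edge
        intensity ramp misclassifies systematically).  0 disables.
    plant_erase_px : int
        Radius around each synthetic plant erased from the detection mask.
        Must cover not just the plant discs but their wavelet-highpass
        halo (a level-2 db4 response extends ~2 * filter length beyond a
        point feature), otherwise every plant leaves a ring of spurious
        detections around its erased core.
    seed : int
        Master seed; per-stage seeds are derived from it.

    Attributes (after ``fit``)
    ----------
    k_, breast_mask_, std_model_, hybrid_, features_, training_,
    mc_params_, bg_params_, diagnostic_
    """

    def __init__(
        self,
        k: Optional[float] = None,
        tissue: Optional[Tissue] = None,
        n_synth_clusters: int = 4,
        synth_mcs_per_cluster: int = 4,
        synth_mc_radius_range: tuple[float, float] = (1.0, 2.5),
        synth_cluster_radius: float = 15.0,
        bg_total: int = 4300,
        window: int = 9,
        wavelet: str = "db4",
        levels: int = 2,
        extension: str = "symmetric",
        block_px: int = 50,
        min_count: int = 3,
        smoothing_sigma: float = 0.8,
        border_margin_px: int = 5,
        plant_erase_px: int = 14,
        seed: int = 0,
    ):
        self.k = k
        self.tissue = tissue
        self.n_synth_clusters = n_synth_clusters
        self.synth_mcs_per_cluster = synth_mcs_per_cluster
        self.synth_mc_radius_range = synth_mc_radius_range
        self.synth_cluster_radius = synth_cluster_radius
        self.bg_total = bg_total
        self.window = window
        self.wavelet = wavelet
        self.levels = levels
        self.extension = extension
        self.block_px = block_px
        self.min_count = min_count
        self.smoothing_sigma = smoothing_sigma
        self.border_margin_px = border_margin_px
        self.plant_erase_px = plant_erase_px
        self.seed = seed

    # ------------------------------------------------------------------ fit

    def fit(
        self,
        image: GrayImage,
        annotations: Sequence[BreastAnnotation] = (),
    ) -> "MicrocalcificationDetector":
        """Learn both class densities from ``image`` itself.

        ``annotations`` (known real lesions) are used only as exclusion
        zones: the synthetic plants and the background ROIs avoid them so
        neither training set is contaminated.
        """
        if self.k is not None and not (0 < self.k <= 1):
            raise ValueError(f"k={self.k} outside (0, 1]")
        ss = np.random.SeedSequence(self.seed)
        rng_place, rng_model, rng_roi = [np.random.default_rng(s) for s in ss.spawn(3)]

        self.image_ = image
        self.breast_mask_ = breast_mask(image)
        self.k_ = (
            self.k
            if self.k is not None
            else choose_k(image, self.breast_mask_, tissue_hint=self.tissue)
        )
        exclusion = [
            (a.center_row, a.center_col, a.radius_px) for a in annotations if a.has_location
        ]
        clusters = self._place_synthetic_clusters(rng_place, exclusion)
        self.std_model_ = make_std_model(
            image.shape, clusters, seed=int(rng_model.integers(0, 2**31 - 1))
        )
        model = MCModel(self.std_model_, self.k_, H=gaussian_kernel(3, self.smoothing_sigma))
        self.hybrid_ = blend(image, model)
        self.features_ = stack_features(
            self.hybrid_.pixels,
            WaveletSpec(self.wavelet, self.levels, self.extension),
            window=self.window,
        )
        within = ndimage.binary_erosion(self.breast_mask_, iterations=2)
        roi_seed = int(rng_roi.integers(0, 2**31 - 1))
        try:
            self.training_ = select_training_samples(
                self.std_model_, image.shape, bg_total=self.bg_total,
                seed=roi_seed, exclusion=exclusion, within=within,
            )
        except RuntimeError:
            # small/odd breast: fall back to image-wide ROI placement
            self.training_ = select_training_samples(
                self.std_model_, image.shape, bg_total=self.bg_total,
                seed=roi_seed, exclusion=exclusion, within=None,
            )
        self.mc_params_ = estimate_params(self.features_, self.training_.mc_coords)
        self.bg_params_ = estimate_params(self.features_, self.training_.bg_coords)
        self.diagnostic_ = mean_difference_diagnostic(
            self.mc_params_, self.bg_params_, self.hybrid_.pixels,
            self.breast_mask_, self.std_model_,
        )
        return self

    def _place_synthetic_clusters(
        self,
        rng: np.random.Generator,
        exclusion: Sequence[tuple[int, int, float]],
        max_tries: int = 500,
    ) -> list[ClusterSpec]:
        margin = int(np.ceil(self.synth_cluster_radius)) + 5
        interior = ndimage.binary_erosion(self.breast_mask_, iterations=margin)
        if not interior.any():
            raise RuntimeError("breast region too small to host synthetic clusters")
        candidates = np.argwhere(interior)
        min_sep = 2.0 * self.synth_cluster_radius + 30.0
        centers: list[tuple[int, int]] = []
        for _ in range(max_tries):
            r, c = candidates[rng.integers(len(candidates))]
            if any((r - er) ** 2 + (c - ec) ** 2 <= (rad + self.synth_cluster_radius + 5) ** 2
                   for er, ec, rad in exclusion):
                continue
            if any((r - r0) ** 2 + (c - c0) ** 2 < min_sep**2 for r0, c0 in centers):
                continue
            centers.append((int(r), int(c)))
            if len(centers) == self.n_synth_clusters:
                break
        if len(centers) < self.n_synth_clusters:
            raise RuntimeError(
                f"could not place {self.n_synth_clusters} synthetic clusters "
                f"after {max_tries} tries"
            )
        return [
            ClusterSpec(center=ctr, n_mcs=self.synth_mcs_per_cluster,
                        mc_radius_range=self.synth_mc_radius_range,
                        cluster_radius_px=self.synth_cluster_radius)
            for ctr in centers
        ]

    # -------------------------------------------------------------- predict

    def predict(self, image: Optional[GrayImage] = None) -> DetectionMask:
        """Segment microcalcifications; None means the fitted image.

        The raw per-pixel classification is cleaned up by (1) erasing the
        known synthetic plants (they are training material, not findings),
        (2) vetoing detections outside the breast mask and suppressing
        components that touch the breast border zone, and (3) the
        cluster-physiology rule.
        """
        check_is_fitted(self, "mc_params_")
        if image is None or image is self.image_:
            feats = self.features_
            breast = self.breast_mask_
            erase_plants = True
        else:
            feats = stack_features(
                image, WaveletSpec(self.wavelet, self.levels, self.extension),
                window=self.window,
            )
            breast = breast_mask(image)
            erase_plants = False

        raw = classify(feats, self.mc_params_, self.bg_params_)
        labels = raw.labels.copy()
        if erase_plants and self.plant_erase_px > 0:
            plant_zone = ndimage.binary_dilation(
                self.std_model_.astype(bool),
                structure=np.ones((3, 3)),
                iterations=self.plant_erase_px,
            )
            labels[plant_zone] = 0
        if self.border_margin_px > 0:
            labels = _suppress_border_components(labels, breast, self.border_margin_px)
        self.raw_mask_ = DetectionMask(labels)
        self.mask_ = apply_physiology_filter(
            self.raw_mask_, breast, block_px=self.block_px, min_count=self.min_count
        )
        return self.mask_

    def fit_predict(
        self,
        image: GrayImage,
        annotations: Sequence[BreastAnnotation] = (),
    ) -> DetectionMask:
        return self.fit(image, annotations).predict()


def _suppress_border_components(
    labels: np.ndarray, breast: np.ndarray, margin_px: int
) -> np.ndarray:
    """Drop whole detection components touching the breast-border zone.

    The intensity ramp at the breast outline misclassifies as a connected
    band; removing any component that intersects the ``margin_px``-wide ring
    just inside the breast kills the band without fragmenting it into
    spurious isolated detections.
    """
    breast = np.asarray(breast).astype(bool)
    ring = breast & ~ndimage.binary_erosion(breast, iterations=margin_px)
    lab, n = ndimage.label(labels.astype(bool), structure=np.ones((3, 3)))
    if n == 0:
        return labels
    touching = np.unique(lab[ring & (lab > 0)])
    out = labels.copy()
    out[np.isin(lab, touching)] = 0
    return out


def detect(
    image: GrayImage,
    annotations: Sequence[BreastAnnotation] = (),
    **params,
) -> dict:
    """One-call detection; returns masks, parameters and diagnostics."""
    det = MicrocalcificationDetector(**params)
    mask = det.fit_predict(image, annotations)
    return {
        "detector": det,
        "mask": mask,
        "raw_mask": det.raw_mask_,
        "k": det.k_,
        "breast_mask": det.breast_mask_,
        "mc_params": det.mc_params_,
        "bg_params": det.bg_params_,
        "diagnostic": det.diagnostic_,
    }


@dataclass
class StudyResult:
    """Aggregate outcome of a seeded multi-phantom detection study."""

    n_images: int
    n_clusters_total: int
    n_clusters_detected: int
    cluster_sensitivity_pct: float
    specificity_pct: float
    fp_per_image: float
    fp_per_image_87: float
    mean_nmd: float
    reports: list[BlockReport] = field(repr=False)
    reports_87: list[BlockReport] = field(repr=False)
    nmds: list[float] = field(repr=False)


def run_phantom_study(
    seed: int,
    n_fatty: int = 5,
    n_dense: int = 5,
    shape: tuple[int, int] = (512, 512),
    mc_contrast: float = 70.0,
    n_clusters: int = 3,
) -> StudyResult:
    """Run the detector over seeded phantoms and score it block-wise.

    Fatty phantoms are processed at K = 0.5 and dense ones at K = 0.2 (via
    the tissue hint).  A planted cluster counts as detected when at least
    one surviving detection component centroid lies inside its truth
    circle; false positives follow the >= 3-centroids-per-50-px-block rule
    (and, for comparison, the 1-centroid-per-87-px-block variant).
    """
    ss = np.random.SeedSequence(seed)
    child = ss.spawn(n_fatty + n_dense)
    plan = ["fatty"] * n_fatty + ["dense"] * n_dense

    reports, reports_87, nmds = [], [], []
    hits = total = 0
    for tissue, cs in zip(plan, child):
        s1, s2 = [int(np.random.default_rng(c).integers(0, 2**31 - 1)) for c in cs.spawn(2)]
        spec = PhantomSpec(shape=shape, tissue=tissue, mc_contrast=mc_contrast,
                           n_clusters=n_clusters, seed=s1)
        image, truth, annotations = generate_phantom(spec)
        nmds.append(phantom_nmd(image, truth, _phantom_breast(image)))

        det = MicrocalcificationDetector(
            tissue=Tissue.DENSE_GLANDULAR if tissue == "dense" else Tissue.FATTY,
            seed=s2,
        )
        mask = det.fit_predict(image, annotations)
        report = label_blocks(mask, annotations, block_px=50, fp_min_count=3)
        reports.append(report)
        reports_87.append(evaluate_variant_87(mask, annotations))
        hits += sum(report.region_hits)
        total += len(report.region_hits)

    specs = [r.specificity for r in reports if r.specificity is not None]
    return StudyResult(
        n_images=len(plan),
        n_clusters_total=total,
        n_clusters_detected=hits,
        cluster_sensitivity_pct=100.0 * hits / total if total else float("nan"),
        specificity_pct=float(np.mean(specs)) if specs else float("nan"),
        fp_per_image=fp_per_image(reports),
        fp_per_image_87=fp_per_image(reports_87),
        mean_nmd=float(np.mean(nmds)),
        reports=reports,
        reports_87=reports_87,
        nmds=nmds,
    )


def _phantom_breast(image: GrayImage) -> np.ndarray:
    return breast_mask(image)
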