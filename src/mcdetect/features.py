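"""Per-pixel feature extraction: the four-channel stack.

Every pixel of a mammogram is described by a 4-vector

    x = [x1, x2, x3, x4]

    x1  graylevel (raw intensity),
    x2  local-maximum rank: the fraction of the 9x9 neighborhood strictly
        below the center pixel (1.0 at a strict local maximum),
    x3  wavelet highpass response: the image reconstructed from the detail
        subbands of a 2-level db4 decomposition after zeroing the deepest
        approximation (bright point anomalies survive, the smooth tissue
        background does not),
    x4  point-singularity measure ED8: the sum of absolute graylevel
        differences to the 8-connected neighbors.

Microcalcifications are small bright spots, so they score high on all four
channels simultaneously; the Gaussian Bayes classifier operates on this
stack.  Channels are spatially registered — the vector at (i, j) reads the
four rasters at (i, j).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pywt
from sklearn.base import BaseEstimator, TransformerMixin

from .imagery import GrayImage

__all__ = [
    "WaveletSpec",
    "FeatureStack",
    "FeatureStackTransformer",
    "graylevel_feature",
    "local_max_rank",
    "wavelet_highpass",
    "ed8",
    "stack_features",
]

CHANNEL_NAMES = ("graylevel", "local_max_rank", "wavelet_highpass", "ed8")


@dataclass
class WaveletSpec:
    """Wavelet decomposition settings for the highpass feature."""

    family: str = "db4"
    levels: int = 2
    extension: str = "symmetric"

    def __post_init__(self) -> None:
        if self.levels < 1:
            raise ValueError("levels must be >= 1")

    @property
    def filter_length(self) -> int:
        return pywt.Wavelet(self.family).dec_len


@dataclass
class FeatureStack:
    """Four spatially-registered feature rasters, shape (h, w, 4)."""

    channels: np.ndarray

    def __post_init__(self) -> None:
        if self.channels.ndim != 3 or self.channels.shape[2] != 4:
            raise ValueError("channels must have shape (h, w, 4)")
        if not np.all(np.isfinite(self.channels)):
            raise ValueError("feature stack contains non-finite values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.channels.shape[:2]

    def vectors_at(self, coords: np.ndarray) -> np.ndarray:
        """Feature matrix (n, 4) at the given (row, col) coordinates."""
        coords = np.asarray(coords)
        return self.channels[coords[:, 0], coords[:, 1], :]

    def as_matrix(self) -> np.ndarray:
        """All pixels as an (h*w, 4) design matrix (row-major order)."""
        return self.channels.reshape(-1, 4)


def graylevel_feature(image: GrayImage) -> np.ndarray:
    """x1: identity copy of the image intensities."""
    return image.pixels.copy()


def local_max_rank(image: GrayImage, window: int = 9) -> np.ndarray:
    """x2: rank of each pixel within its local window histogram.

    rank(i, j) = #{neighbors strictly below the center} / (window^2 - 1),
    computed over the window x window neighborhood with replicate padding.
    The value is 1.0 exactly when the center is a strict local maximum and
    0.0 on constant patches; it is invariant under any strictly monotone
    intensity remapping.
    """
    if window % 2 == 0 or window < 3:
        raise ValueError("window must be odd and >= 3")
    img = image.pixels
    pad = window // 2
    padded = np.pad(img, pad, mode="edge")
    count = np.zeros_like(img)
    h, w = img.shape
    for dr in range(-pad, pad + 1):
        for dc in range(-pad, pad + 1):
            if dr == 0 and dc == 0:
                continue
            shifted = padded[pad + dr : pad + dr + h, pad + dc : pad + dc + w]
            count += shifted < img
    return count / (window * window - 1)


def wavelet_highpass(image: GrayImage, spec: Optional[WaveletSpec] = None) -> np.ndarray:
    """x3: reconstruction from detail subbands only (signed response).

    The image is decomposed with a separable 2-D DWT to ``spec.levels``,
    the deepest approximation subband is zeroed, and the inverse transform
    is taken; the smooth background lives in the approximation and is
    thereby suppressed while point anomalies persist in the details.
    """
    spec = spec or WaveletSpec()
    img = image.pixels
    if min(img.shape) < spec.filter_length:
        raise ValueError(
            f"image {img.shape} smaller than the {spec.family} filter support "
            f"({spec.filter_length})"
        )
    coeffs = pywt.wavedec2(img, spec.family, mode=spec.extension, level=spec.levels)
    coeffs[0] = np.zeros_like(coeffs[0])
    rec = pywt.waverec2(coeffs, spec.family, mode=spec.extension)
    return rec[: img.shape[0], : img.shape[1]]


_ED8_OFFSETS = [(k2, k1) for k2 in (-1, 0, 1) for k1 in (-1, 0, 1)]


def ed8(image: GrayImage) -> np.ndarray:
    """x4: sum of absolute graylevel differences to the 8 neighbors.

    ED8(i, j) = sum over k1, k2 in {-1, 0, 1} of |I(i+k2, j+k1) - I(i, j)|
    (the k1 = k2 = 0 term contributes zero), with replicate padding at the
    borders.  Isolated bright points score ~8x their local contrast.
    """
    img = image.pixels
    h, w = img.shape
    padded = np.pad(img, 1, mode="edge")
    out = np.zeros_like(img)
    for dr, dc in _ED8_OFFSETS:
        shifted = padded[1 + dr : 1 + dr + h, 1 + dc : 1 + dc + w]
        out += np.abs(shifted - img)
    return out


def stack_features(
    image: GrayImage,
    spec: Optional[WaveletSpec] = None,
    window: int = 9,
) -> FeatureStack:
    """Compute all four channels and stack them as (h, w, 4)."""
    channels = np.stack(
        [
            graylevel_feature(image),
            local_max_rank(image, window=window),
            wavelet_highpass(image, spec),
            ed8(image),
        ],
        axis=-1,
    )
    return FeatureStack(channels)


class FeatureStackTransformer(BaseEstimator, TransformerMixin):
    """sklearn-style transformer wrapping :func:`stack_features`.

    ``transform`` maps a :class:`GrayImage` (or bare 2-D array) to the
    (h, w, 4) channel stack; ``fit`` is stateless and returns self.
    """

    def __init__(self, family: str = "db4", levels: int = 2,
                 extension: str = "symmetric", window: int = 9):
        self.family = family
        self.levels = levels
        self.extension = extension
        self.window = window

    def fit(self, X=None, y=None):
        return self

    def transform(self, X) -> np.ndarray:
        image = X if isinstance(X, GrayImage) else GrayImage(np.asarray(X))
        spec = WaveletSpec(self.family, self.levels, self.extension)
        return stack_features(image, spec, window=self.window).channels


def save_channels(stack: FeatureStack, directory, prefix: str = "feature") -> list:
    """Write each channel as an 8-bit PNG for visual inspection.

    The signed wavelet channel is shifted/scaled to [0, 255] for display
    only; in-memory data stays signed.  Returns the written paths.
    """
    from pathlib import Path

    from .imagery import write_gray

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, name in enumerate(CHANNEL_NAMES):
        ch = stack.channels[..., i].astype(np.float64)
        lo, hi = ch.min(), ch.max()
        disp = (ch - lo) * (255.0 / (hi - lo)) if hi > lo else np.zeros_like(ch)
        path = directory / f"{prefix}_{i + 1}_{name}.png"
        write_gray(GrayImage(disp), path)
        paths.append(path)
    return paths
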