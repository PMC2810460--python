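"""Raster and annotation I/O for mammographic images.

Images are carried as real-valued 2-D arrays in the nominal 8-bit range
[0, 255] together with the detector pixel pitch (mini-MIAS convention:
1024x1024 px at 200 um/pixel).  All pixel coordinates in this package are
0-based ``(row, col)`` with row 0 at the top of the image; the MIAS
bottom-left annotation convention is converted at parse time and nowhere
else.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
from PIL import Image

__all__ = [
    "GrayImage",
    "BreastAnnotation",
    "Tissue",
    "Abnormality",
    "Severity",
    "FormatError",
    "AnnotationParseError",
    "read_gray",
    "write_gray",
    "parse_mias_annotations",
    "mias_row_to_internal",
]

#: mini-MIAS spatial resolution, microns per pixel.
DEFAULT_PIXEL_PITCH_UM = 200.0


class FormatError(ValueError):
    """Raised when an image file cannot be interpreted as single-channel gray."""


class AnnotationParseError(ValueError):
    """Raised when a MIAS annotation record is malformed."""


class Tissue(str, enum.Enum):
    """MIAS background-tissue classes."""

    FATTY = "fatty"
    FATTY_GLANDULAR = "fatty-glandular"
    DENSE_GLANDULAR = "dense-glandular"


class Abnormality(str, enum.Enum):
    """MIAS abnormality classes (CALC = calcification)."""

    CALC = "CALC"
    CIRC = "CIRC"
    SPIC = "SPIC"
    MISC = "MISC"
    ARCH = "ARCH"
    ASYM = "ASYM"
    NORM = "NORM"


class Severity(str, enum.Enum):
    BENIGN = "benign"
    MALIGNANT = "malignant"
    NONE = "none"


_TISSUE_CODES = {
    "F": Tissue.FATTY,
    "G": Tissue.FATTY_GLANDULAR,
    "D": Tissue.DENSE_GLANDULAR,
}
_SEVERITY_CODES = {"B": Severity.BENIGN, "M": Severity.MALIGNANT}


@dataclass
class GrayImage:
    """A 2-D grayscale raster with physical pixel-pitch metadata.

    Parameters
    ----------
    pixels
        2-D float array of intensities, nominal range [0, 255].  Values are
        stored as real numbers; quantization happens only on write.
    pixel_pitch_um
        Detector sampling pitch in microns per pixel (default 200, the
        mini-MIAS digitization).
    """

    pixels: np.ndarray
    pixel_pitch_um: float = DEFAULT_PIXEL_PITCH_UM

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError(f"pixels must be 2-D, got shape {self.pixels.shape}")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("image must have at least one row and one column")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixels must all be finite")
        if self.pixel_pitch_um <= 0:
            raise ValueError("pixel_pitch_um must be positive")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class BreastAnnotation:
    """One MIAS-style finding: reference id, tissue, abnormality, location.

    ``center_row``/``center_col`` use this package's top-left 0-based
    convention.  Normal records (no finding) carry ``None`` for the location
    fields and ``radius_px`` 0.
    """

    ref_id: str
    tissue: Tissue
    abnormality: Abnormality
    severity: Severity = Severity.NONE
    center_row: Optional[int] = None
    center_col: Optional[int] = None
    radius_px: float = 0.0

    @property
    def has_location(self) -> bool:
        return self.center_row is not None and self.center_col is not None

    def __post_init__(self) -> None:
        if self.radius_px < 0:
            raise ValueError("radius_px must be non-negative")


def read_gray(path: Union[str, Path]) -> GrayImage:
    """Read a PGM (P2/P5) or PNG grayscale file into a :class:`GrayImage`.

    16-bit inputs are linearly rescaled so that 65535 maps to 255.  Color
    images whose channels are not all identical raise :class:`FormatError`.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            im.load()
            mode = im.mode
            arr = np.asarray(im)
    except (OSError, SyntaxError) as exc:
        raise FormatError(f"cannot read image file {path}: {exc}") from exc

    if arr.ndim == 3:
        # accept "color" files that are really gray (all channels equal)
        rgb = arr[..., :3]
        if not (rgb[..., 0] == rgb[..., 1]).all() or not (rgb[..., 0] == rgb[..., 2]).all():
            raise FormatError(f"{path} is a color image with no single-channel representation")
        arr = rgb[..., 0]

    arr = arr.astype(np.float64)
    if mode in ("I", "I;16", "I;16B", "I;16L") or arr.max(initial=0.0) > 255:
        arr = arr * (255.0 / 65535.0)
    return GrayImage(arr)


def write_gray(image: GrayImage, path: Union[str, Path]) -> None:
    """Write an image as 8-bit PGM (``.pgm``) or PNG (``.png``).

    Values are clipped to [0, 255] and rounded to the nearest integer, so a
    write/read round trip is bit-exact for already-quantized 8-bit data.
    """
    path = Path(path)
    data = np.clip(np.rint(image.pixels), 0, 255).astype(np.uint8)
    try:
        Image.fromarray(data, mode="L").save(path)
    except OSError as exc:
        raise OSError(f"cannot write image file {path}: {exc}") from exc


def mias_row_to_internal(y: int, image_height: int) -> int:
    """Convert a MIAS bottom-left y coordinate to a top-left row index."""
    return image_height - 1 - y


def parse_mias_annotations(text: str, image_height: int) -> list[BreastAnnotation]:
    """Parse MIAS plain-text annotation records.

    Each non-empty line is ``ref tissue class [severity x y radius]`` with x
    measured from the left and y from the *bottom* of the image; coordinates
    are flipped to this package's top-left row convention via
    ``row = image_height - 1 - y``.  Records without a location (NORM cases)
    yield annotations with no location.
    """
    annotations: list[BreastAnnotation] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        tokens = line.split()
        if len(tokens) not in (3, 7):
            raise AnnotationParseError(
                f"line {lineno}: expected 3 or 7 fields, got {len(tokens)}: {line!r}"
            )
        ref, tissue_code, abn_code = tokens[:3]
        try:
            tissue = _TISSUE_CODES[tissue_code]
        except KeyError:
            raise AnnotationParseError(f"line {lineno}: unknown tissue code {tissue_code!r}")
        try:
            abnormality = Abnormality(abn_code)
        except ValueError:
            raise AnnotationParseError(f"line {lineno}: unknown abnormality code {abn_code!r}")

        if len(tokens) == 3:
            annotations.append(BreastAnnotation(ref, tissue, abnormality))
            continue

        sev_code, x_s, y_s, r_s = tokens[3:]
        try:
            severity = _SEVERITY_CODES[sev_code]
        except KeyError:
            raise AnnotationParseError(f"line {lineno}: unknown severity code {sev_code!r}")
        try:
            x, y, radius = int(x_s), int(y_s), float(r_s)
        except ValueError:
            raise AnnotationParseError(f"line {lineno}: non-numeric location fields: {line!r}")
        annotations.append(
            BreastAnnotation(
                ref,
                tissue,
                abnormality,
                severity=severity,
                center_row=mias_row_to_internal(y, image_height),
                center_col=x,
                radius_px=radius,
            )
        )
    return annotations


def format_mias_annotations(annotations: Sequence[BreastAnnotation], image_height: int) -> str:
    """Inverse of :func:`parse_mias_annotations` (used by the phantom writer)."""
    code_for_tissue = {v: k for k, v in _TISSUE_CODES.items()}
    code_for_sev = {v: k for k, v in _SEVERITY_CODES.items()}
    lines = []
    for a in annotations:
        if a.has_location:
            y = image_height - 1 - int(a.center_row)
            sev = code_for_sev.get(a.severity, "B")
            lines.append(
                f"{a.ref_id} {code_for_tissue[a.tissue]} {a.abnormality.value} "
                f"{sev} {int(a.center_col)} {y} {int(round(a.radius_px))}"
            )
        else:
            lines.append(f"{a.ref_id} {code_for_tissue[a.tissue]} {a.abnormality.value}")
    return "\n".join(lines) + "\n"
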