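"""Raster I/O, grayscale promotion and mirror padding.

Every stage of the pipeline works on three-channel 8-bit images.  Grayscale
inputs are promoted to three identical planes on load (the method then treats
each plane independently, so impulses can hit any plane of a promoted image).
All coordinates in this package are 0-based, row-major; the mirror-padding
convention defined here (reflection *without* repeating the border pixel,
``abc -> b|abc|b``) is the single convention shared by detection and
restoration.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

#: file suffixes accepted for lossless round-tripping
_LOSSLESS_SUFFIXES = {".png", ".tif", ".tiff", ".pgm", ".ppm", ".pnm", ".bmp"}


@dataclass
class ColorImage:
    """A three-plane 8-bit image plus provenance.

    ``data`` has shape (n, m, 3), dtype uint8.  ``provenance`` records whether
    the source file was genuinely colour or a single-plane image promoted to
    three identical layers.
    """

    data: np.ndarray
    provenance: str = "color"  # "color" | "promoted-grayscale"

    def __post_init__(self) -> None:
        self.data = validate_image(self.data)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_rows(self) -> int:
        return self.data.shape[0]

    @property
    def n_cols(self) -> int:
        return self.data.shape[1]


def validate_image(arr: np.ndarray) -> np.ndarray:
    """Check that ``arr`` is an (n, m, 3) uint8 array and return it."""
    arr = np.asarray(arr)
    if arr.dtype != np.uint8:
        raise ValidationError(f"expected 8-bit image data, got dtype {arr.dtype}")
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValidationError(f"expected shape (n, m, 3), got {arr.shape}")
    return arr


def promote_grayscale(plane: np.ndarray) -> ColorImage:
    """Replicate a single 8-bit plane into three identical channels."""
    plane = np.asarray(plane)
    if plane.dtype != np.uint8:
        raise ValidationError(f"expected 8-bit plane, got dtype {plane.dtype}")
    if plane.ndim != 2:
        raise ValidationError(f"expected a 2-D plane, got shape {plane.shape}")
    return ColorImage(np.repeat(plane[:, :, None], 3, axis=2), "promoted-grayscale")


def load_image(path: str | Path) -> ColorImage:
    """Load a PNG/TIFF/PGM/PPM raster as a :class:`ColorImage`.

    Single-plane files are promoted to three identical planes; alpha channels
    are dropped with a logged warning; non-8-bit files are rejected because the
    impulse model is defined on the {0, 255} extremes.
    """
    path = Path(path)
    try:
        arr = iio.imread(path)
    except Exception as exc:  # imageio raises various backends' errors
        raise FormatError(f"cannot read image file {path}: {exc}") from exc
    if arr.dtype != np.uint8:
        raise FormatError(
            f"{path}: only 8-bit images are supported (got dtype {arr.dtype})"
        )
    if arr.ndim == 2:
        return promote_grayscale(arr)
    if arr.ndim == 3 and arr.shape[2] == 4:
        logger.warning("%s: dropping alpha channel", path)
        warnings.warn(f"{path}: alpha channel dropped", stacklevel=2)
        arr = arr[:, :, :3]
    if arr.ndim == 3 and arr.shape[2] == 3:
        if bool(np.all(arr[:, :, 0] == arr[:, :, 1]) and np.all(arr[:, :, 1] == arr[:, :, 2])):
            # three identical planes stored in the file: keep colour provenance,
            # the distinction only matters for files loaded as single-plane
            return ColorImage(arr.copy(), "color")
        return ColorImage(arr.copy(), "color")
    raise FormatError(f"{path}: unsupported layout with shape {arr.shape}")


def save_image(image: ColorImage, path: str | Path, *, as_grayscale: bool | None = None) -> None:
    """Write ``image`` losslessly (PNG/TIFF/PGM/PPM only).

    Promoted-grayscale images may be written back as a single plane by passing
    ``as_grayscale=True`` (the default writes whatever provenance suggests for
    PGM, three planes otherwise).  Lossy targets such as JPEG are refused.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix not in _LOSSLESS_SUFFIXES:
        raise FormatError(
            f"refusing to write {path}: {suffix or '<no suffix>'} is not a "
            "supported lossless format (use PNG/TIFF/PGM/PPM)"
        )
    data = validate_image(image.data)
    if as_grayscale is None:
        as_grayscale = suffix == ".pgm"
    if as_grayscale:
        if image.provenance != "promoted-grayscale" and not np.all(
            (data[:, :, 0] == data[:, :, 1]) & (data[:, :, 1] == data[:, :, 2])
        ):
            raise FormatError("cannot write a genuine colour image as single-plane")
        data = data[:, :, 0]
    try:
        iio.imwrite(path, data)
    except OSError as exc:
        raise IOError(f"cannot write image file {path}: {exc}") from exc


def save_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a boolean (n, m) mask as a single-plane PNG/PGM (255 = flagged)."""
    mask = np.asarray(mask)
    if mask.ndim != 2 or mask.dtype != np.bool_:
        raise ValidationError(f"expected a boolean (n, m) mask, got {mask.shape} {mask.dtype}")
    path = Path(path)
    if path.suffix.lower() not in _LOSSLESS_SUFFIXES:
        raise FormatError(f"refusing lossy/unknown mask format: {path.suffix}")
    iio.imwrite(path, (mask.astype(np.uint8) * 255))


def mirror_pad(plane: np.ndarray, ms: int) -> np.ndarray:
    """Mirror-pad a 2-D plane by ``ms`` pixels on every side.

    Reflection excludes the border pixel itself: the row ``[a, b, c]`` padded
    by one becomes ``[b, a, b, c, b]``.  With the default windows
    (main 7, secondary 5) the pad size is floor(7/2) + floor(5/2) = 5.
    """
    plane = np.asarray(plane)
    if plane.ndim != 2:
        raise ValidationError(f"expected a 2-D plane, got shape {plane.shape}")
    if ms < 0:
        raise ValidationError(f"pad size must be non-negative, got {ms}")
    if ms >= plane.shape[0] or ms >= plane.shape[1]:
        raise ValidationError(
            f"pad size {ms} must be smaller than both image dimensions {plane.shape}"
        )
    if ms == 0:
        return plane.copy()
    return np.pad(plane, ms, mode="reflect")
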