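"""Grayscale image container and file I/O.

Everything in the package operates on :class:`Image2D`: a rectangular grid of
real-valued intensities together with a *nominal* bit depth (the dynamic range
the values are meant to live in, e.g. ``[0, 4095]`` for 12-bit radiographs).
Intensities are carried as floats internally — diffusion solves are
continuous-valued — and quantized only when an image is written to disk.

Coordinate convention, used consistently across the package: ``(x, y)`` means
``(column, row)``, 0-based, origin at the top-left.  NumPy arrays are indexed
``pixels[y, x]``.

Supported containers: 8/16-bit single-channel PNG and TIFF, plus the headerless
raw layout of the JSRT chest-radiograph collection (2048x2048 pixels, 16-bit
big-endian, row-major from the top-left, 12 bits of useful dynamic range).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import imageio.v3 as iio
import numpy as np

from .exceptions import DimensionError, FormatError, RangeError

__all__ = ["Image2D", "read_image", "write_image", "read_jsrt_raw"]

_ALLOWED_BIT_DEPTHS = (8, 12, 16)
_JSRT_SHAPE = (2048, 2048)
_JSRT_SPACING_MM = (0.175, 0.171)


@dataclass
class Image2D:
    """A single-channel image: float pixel grid plus nominal bit depth.

    Parameters
    ----------
    pixels
        2-D array of finite real intensities, indexed ``[row, column]``.
    bit_depth
        Nominal dynamic range is ``[0, 2**bit_depth - 1]``; one of 8, 12, 16.
        Radiographs are conventionally 12-bit.
    pixel_spacing_mm
        Optional ``(row_spacing, column_spacing)`` in millimetres.
    """

    pixels: np.ndarray
    bit_depth: int = 12
    pixel_spacing_mm: tuple[float, float] | None = field(default=None)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2:
            raise DimensionError(f"pixels must be 2-D, got {px.ndim}-D")
        if px.shape[0] < 3 or px.shape[1] < 3:
            raise DimensionError(
                f"image must be at least 3x3 (central differences need an "
                f"interior), got {px.shape[0]}x{px.shape[1]}"
            )
        if not np.all(np.isfinite(px)):
            raise ValueError("pixels contain NaN or Inf")
        if self.bit_depth not in _ALLOWED_BIT_DEPTHS:
            raise ValueError(
                f"bit_depth must be one of {_ALLOWED_BIT_DEPTHS}, got {self.bit_depth}"
            )
        if self.pixel_spacing_mm is not None:
            sy, sx = self.pixel_spacing_mm
            if sy <= 0 or sx <= 0:
                raise ValueError("pixel spacings must be positive")
            self.pixel_spacing_mm = (float(sy), float(sx))
        self.pixels = px

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def intensity_max(self) -> float:
        """Upper end of the nominal dynamic range, ``2**bit_depth - 1``."""
        return float(2**self.bit_depth - 1)

    def with_pixels(self, pixels: np.ndarray) -> "Image2D":
        """A new image with the same metadata and a different pixel grid."""
        return Image2D(pixels, bit_depth=self.bit_depth,
                       pixel_spacing_mm=self.pixel_spacing_mm)


def read_image(path: str | os.PathLike, bit_depth_hint: int | None = None) -> Image2D:
    """Read an 8/16-bit single-channel PNG or TIFF into an :class:`Image2D`.

    Values are returned exactly as stored, with no rescaling.  ``bit_depth`` is
    taken from ``bit_depth_hint`` when given (e.g. 12 for radiograph data held
    in 16-bit containers), otherwise from the container depth.
    """
    arr = iio.imread(path)
    if arr.ndim == 3:
        raise FormatError(
            f"{path}: expected a single-channel image, got {arr.shape[2]} channels"
        )
    if arr.ndim != 2:
        raise FormatError(f"{path}: unsupported image dimensionality {arr.ndim}")
    container_depth = 8 if arr.dtype.itemsize == 1 else 16
    return Image2D(arr.astype(np.float64),
                   bit_depth=bit_depth_hint if bit_depth_hint is not None
                   else container_depth)


def write_image(img: Image2D, path: str | os.PathLike) -> None:
    """Write ``img`` as a 16-bit single-channel PNG or TIFF (by extension).

    Intensities are rounded to the nearest integer at write time.  Values must
    already lie in ``[0, 65535]``: range handling (clipping or rescaling) is a
    policy decision that belongs to the caller, see
    :func:`radusm.enhance.usm_enhance`.
    """
    ext = os.path.splitext(os.fspath(path))[1].lower()
    if ext not in (".png", ".tif", ".tiff"):
        raise FormatError(f"unsupported output extension {ext!r} (use .png/.tif/.tiff)")
    px = img.pixels
    lo, hi = float(px.min()), float(px.max())
    if lo < 0 or hi > 65535:
        raise RangeError(
            f"intensities [{lo:g}, {hi:g}] outside [0, 65535]; apply a range "
            f"policy (clip or rescale) before writing"
        )
    iio.imwrite(path, np.rint(px).astype(np.uint16))


def read_jsrt_raw(path: str | os.PathLike) -> Image2D:
    """Read a headerless JSRT raw radiograph.

    Layout: exactly 2048x2048 pixels, 16-bit big-endian, row-major with the
    top-left pixel first — the de-facto convention for the dataset's ``.IMG``
    files.  Useful dynamic range is 12 bits; the pixel spacing is
    0.175 mm x 0.171 mm (row x column).
    """
    with open(path, "rb") as fh:
        data = fh.read()
    expected = _JSRT_SHAPE[0] * _JSRT_SHAPE[1] * 2
    if len(data) != expected:
        raise FormatError(
            f"{path}: expected {expected} bytes for a "
            f"{_JSRT_SHAPE[0]}x{_JSRT_SHAPE[1]} 16-bit raw image, got {len(data)}"
        )
    arr = np.frombuffer(data, dtype=">u2").reshape(_JSRT_SHAPE)
    return Image2D(arr.astype(np.float64), bit_depth=12,
                   pixel_spacing_mm=_JSRT_SPACING_MM)
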