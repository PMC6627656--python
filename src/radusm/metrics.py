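"""Quantitative evaluation: blockwise EMEE and a simple region SNR.

EMEE — measurement of enhancement by entropy evaluation — tiles the image
into blocks, computes the stabilized contrast ratio
``r = I_max / (I_min + c)`` per block, and averages the entropy-style weight
``r * ln(r)``.  Higher values mean stronger local contrast.  The constant
``c`` keeps the denominator away from zero (radiographs frequently contain
exactly-zero pixels); ``r = 0`` blocks contribute 0 by the continuity
convention ``0 * ln(0) := 0``.

The logarithm is natural.  Base only rescales every value uniformly, so
comparisons and trends are base-independent, but absolute numbers are not —
hence this prominent note.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .exceptions import ParameterError, UndefinedSNRError
from .image import Image2D

__all__ = ["EMEEConfig", "emee", "snr"]


@dataclass
class EMEEConfig:
    """EMEE tiling and stabilization parameters.

    Defaults: 40x40 blocks with ``c = 30``, the conventional settings for
    12-bit chest radiographs.  Blocks tile from the top-left; partial blocks
    at the right/bottom edges are included as-is so every pixel participates
    (image sides are rarely multiples of the block size).
    """

    block_h: int = 40
    block_w: int = 40
    c: float = 30.0

    def __post_init__(self) -> None:
        if self.block_h < 1 or self.block_w < 1:
            raise ParameterError("block dimensions must be >= 1")
        if self.c <= 0:
            raise ParameterError("c must be > 0")


def emee(img: Image2D, config: EMEEConfig | None = None) -> float:
    """Mean over blocks of ``r * ln(r)`` with ``r = I_max / (I_min + c)``.

    Intended for nonnegative images; a block whose ratio is <= 0 contributes
    0 (the ``r = 0`` case by continuity).
    """
    config = config or EMEEConfig()
    px = img.pixels
    h, w = px.shape
    terms = []
    for top in range(0, h, config.block_h):
        for left in range(0, w, config.block_w):
            block = px[top : top + config.block_h, left : left + config.block_w]
            ratio = float(block.max()) / (float(block.min()) + config.c)
            terms.append(ratio * math.log(ratio) if ratio > 0.0 else 0.0)
    return float(np.mean(terms))


Rect = tuple[int, int, int, int]  # (top, left, height, width)


def snr(img: Image2D, signal_region: Rect, noise_region: Rect) -> float:
    """Mean over ``signal_region`` divided by the sample std over ``noise_region``.

    Regions are ``(top, left, height, width)`` rectangles in pixel
    coordinates.  The noise standard deviation uses the ``n - 1`` denominator
    and must come from a region of at least two pixels.  This is one simple,
    explicit SNR definition among many; absolute values are comparable only
    across identical region protocols.
    """
    sig = _extract(img, signal_region, "signal_region")
    noi = _extract(img, noise_region, "noise_region")
    if noi.size < 2:
        raise ParameterError("noise_region must contain at least 2 pixels")
    sd = float(noi.std(ddof=1))
    if sd == 0.0:
        raise UndefinedSNRError("noise region has zero standard deviation")
    return float(sig.mean()) / sd


def _extract(img: Image2D, rect: Rect, name: str) -> np.ndarray:
    top, left, h, w = rect
    if h < 1 or w < 1:
        raise ParameterError(f"{name} must have positive extent")
    if top < 0 or left < 0 or top + h > img.height or left + w > img.width:
        raise ParameterError(
            f"{name} {rect} exceeds image bounds {img.height}x{img.width}"
        )
    return img.pixels[top : top + h, left : left + w]
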