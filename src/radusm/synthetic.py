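"""Reproducible chest-like phantoms and elementary test patterns.

Real portable chest radiographs are private clinical data, so the package
ships a generator for phantoms that carry the features the enhancement
pipeline cares about: a smooth low-frequency background (mediastinum-like
intensity ramp), smooth periodic horizontal bands standing in for ribs, thin
bright curvilinear "tubes" (the line structures — endotracheal, feeding,
nasogastric tubes — the method is designed to enhance), additive Gaussian
noise, and sparse impulse noise.  Alongside the image the generator returns
ground-truth masks of tube pixels and impulse locations, which is what makes
selectivity claims ("edges smoothed, noise kept") testable.

Everything is a pure function of the spec, including its seed: the same spec
always renders the bit-identical triple.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import make_interp_spline
from scipy.spatial import cKDTree

from .exceptions import PhantomSpecError
from .image import Image2D

__all__ = [
    "TubeSpec",
    "PhantomSpec",
    "make_phantom",
    "make_step_edge",
    "add_impulses",
    "STANDARD_PHANTOM",
    "make_standard_phantom",
]


@dataclass(frozen=True)
class TubeSpec:
    """One curvilinear bright structure.

    ``control_points`` are ``(x, y)`` positions the centerline passes
    through; the curve is a chordal cubic spline (a straight segment for two
    points).  ``width`` is the full width in pixels; ``contrast`` is added on
    top of the local background, exactly, for every pixel within
    ``width / 2`` of the centerline.
    """

    control_points: tuple[tuple[float, float], ...]
    width: float = 3.0
    contrast: float = 600.0


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of a synthetic chest-like test image.

    Background: ``base_level`` plus a vertical ramp of ``gradient_amplitude``
    from top to bottom.  Ribs: a raised-cosine horizontal banding of the
    given amplitude with ``rib_count`` periods over the image height.
    Noise: additive Gaussian with ``gaussian_noise_sigma``, then impulse
    pixels.  The impulse count is exact — ``round(density * n_pixels)``
    positions chosen without replacement — not Bernoulli sampling, so tests
    can assert exact counts.  An impulse pixel is *set* to (noise-free value
    + ``impulse_amplitude``), replacing any Gaussian noise there, so each one
    differs from the clean render by exactly the impulse amplitude.
    """

    height: int = 256
    width: int = 256
    base_level: float = 1500.0
    gradient_amplitude: float = 400.0
    rib_count: int = 5
    rib_amplitude: float = 200.0
    tubes: tuple[TubeSpec, ...] = field(default_factory=tuple)
    gaussian_noise_sigma: float = 20.0
    impulse_density: float = 0.005
    impulse_amplitude: float = 400.0
    seed: int = 0
    bit_depth: int = 12

    def __post_init__(self) -> None:
        if self.height < 3 or self.width < 3:
            raise PhantomSpecError("phantom must be at least 3x3")
        for a in (self.base_level, self.gradient_amplitude, self.rib_amplitude,
                  self.gaussian_noise_sigma, self.impulse_amplitude):
            if not np.isfinite(a):
                raise PhantomSpecError("amplitudes must be finite")
        if self.gaussian_noise_sigma < 0:
            raise PhantomSpecError("gaussian_noise_sigma must be >= 0")
        if not (0.0 <= self.impulse_density <= 0.05):
            raise PhantomSpecError("impulse_density must lie in [0, 0.05]")


def _tube_centerline(tube: TubeSpec, height: int, width: int) -> np.ndarray:
    """Densely sampled (x, y) points of the centerline; bounds-checked."""
    pts = np.asarray(tube.control_points, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] != 2:
        raise PhantomSpecError("a tube needs at least two (x, y) control points")
    # Chordal parameterization keeps the spline well behaved for curves that
    # are not a function of x (e.g. mostly vertical tubes).
    chord = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))])
    if chord[-1] == 0.0:
        raise PhantomSpecError("tube control points are all identical")
    k = min(3, pts.shape[0] - 1)
    spline = make_interp_spline(chord, pts, k=k)
    n_samples = max(16, int(4.0 * chord[-1]))
    samples = spline(np.linspace(0.0, chord[-1], n_samples))
    margin = tube.width / 2.0
    if (samples[:, 0].min() < -margin or samples[:, 0].max() > width - 1 + margin
            or samples[:, 1].min() < -margin or samples[:, 1].max() > height - 1 + margin):
        raise PhantomSpecError("tube leaves the image bounds")
    return samples


def _render_tubes(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Additive tube intensities and the boolean tube-support mask."""
    add = np.zeros((spec.height, spec.width))
    mask = np.zeros((spec.height, spec.width), dtype=bool)
    if not spec.tubes:
        return add, mask
    yy, xx = np.mgrid[0 : spec.height, 0 : spec.width]
    pixel_xy = np.column_stack([xx.ravel(), yy.ravel()]).astype(np.float64)
    for tube in spec.tubes:
        samples = _tube_centerline(tube, spec.height, spec.width)
        dist, _ = cKDTree(samples).query(pixel_xy, k=1)
        support = (dist <= tube.width / 2.0).reshape(spec.height, spec.width)
        add[support] += tube.contrast
        mask |= support
    return add, mask


def make_phantom(spec: PhantomSpec) -> tuple[Image2D, np.ndarray, np.ndarray]:
    """Render a phantom; returns ``(image, edge_map, impulse_map)``.

    ``edge_map`` marks the tube-support pixels — the high-gradient line
    structures the enhancement is supposed to single out.  ``impulse_map``
    marks the impulse-noise pixels.  The final image is clamped to the
    nominal dynamic range.
    """
    h, w = spec.height, spec.width
    y = np.arange(h, dtype=np.float64)[:, None]
    background = spec.base_level + spec.gradient_amplitude * (y / max(h - 1, 1))
    ribs = 0.5 * spec.rib_amplitude * (
        1.0 + np.cos(2.0 * np.pi * spec.rib_count * y / h)
    )
    tube_add, edge_map = _render_tubes(spec)
    clean = np.broadcast_to(background + ribs, (h, w)) + tube_add

    rng = np.random.default_rng(spec.seed)
    noisy = clean + (rng.normal(0.0, spec.gaussian_noise_sigma, (h, w))
                     if spec.gaussian_noise_sigma > 0 else 0.0)

    n_impulses = int(round(spec.impulse_density * h * w))
    impulse_map = np.zeros((h, w), dtype=bool)
    if n_impulses > 0:
        flat = rng.choice(h * w, size=n_impulses, replace=False)
        impulse_map.ravel()[flat] = True
        noisy = noisy.copy()
        noisy.ravel()[flat] = clean.ravel()[flat] + spec.impulse_amplitude

    top = float(2**spec.bit_depth - 1)
    img = Image2D(np.clip(noisy, 0.0, top), bit_depth=spec.bit_depth)
    return img, edge_map, impulse_map


def make_step_edge(height: int, width: int, level_low: float, level_high: float,
                   edge_column: int) -> Image2D:
    """Vertical step: columns ``< edge_column`` at ``level_low``, rest at ``level_high``."""
    if not (0 < edge_column < width):
        raise PhantomSpecError(
            f"edge_column must lie strictly inside (0, {width}), got {edge_column}"
        )
    px = np.full((height, width), float(level_low))
    px[:, edge_column:] = float(level_high)
    return Image2D(px)


def add_impulses(pixels: np.ndarray, density: float, amplitude: float,
                 seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Add an exact count of impulse pixels to a grid.

    ``round(density * n_pixels)`` positions are chosen without replacement by
    a seeded generator and raised by ``amplitude``.  Returns the new grid and
    the boolean impulse map.
    """
    if not (0.0 <= density <= 0.05):
        raise PhantomSpecError("density must lie in [0, 0.05]")
    px = np.array(pixels, dtype=np.float64)
    n = int(round(density * px.size))
    mask = np.zeros(px.shape, dtype=bool)
    if n > 0:
        flat = np.random.default_rng(seed).choice(px.size, size=n, replace=False)
        mask.ravel()[flat] = True
        px.ravel()[flat] += amplitude
    return px, mask


#: The frozen phantom preset used throughout the documentation and the
#: acceptance suite: 256x256, base 1500 with a 400 vertical ramp, 5 rib bands
#: of amplitude 200, two curved width-3 tubes of contrast +600, Gaussian noise
#: sigma 20, 0.5% impulse pixels of amplitude +400, seed 20190424.
STANDARD_PHANTOM = PhantomSpec(
    height=256,
    width=256,
    base_level=1500.0,
    gradient_amplitude=400.0,
    rib_count=5,
    rib_amplitude=200.0,
    tubes=(
        TubeSpec(control_points=((60.0, 16.0), (72.0, 80.0), (92.0, 160.0),
                                 (108.0, 240.0)), width=3.0, contrast=600.0),
        TubeSpec(control_points=((180.0, 12.0), (166.0, 72.0), (150.0, 150.0),
                                 (158.0, 244.0)), width=3.0, contrast=600.0),
    ),
    gaussian_noise_sigma=20.0,
    impulse_density=0.005,
    impulse_amplitude=400.0,
    seed=20190424,
)


def make_standard_phantom() -> tuple[Image2D, np.ndarray, np.ndarray]:
    """Render :data:`STANDARD_PHANTOM`."""
    return make_phantom(STANDARD_PHANTOM)
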