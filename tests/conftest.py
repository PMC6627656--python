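"""Shared fixtures and the dense-matrix oracle used against the matrix-free code."""

import numpy as np
import pytest

from radusm.diffusion import CoefficientField, DiffusionParams, compute_coefficients
from radusm.image import Image2D
from radusm.synthetic import make_standard_phantom


def assemble_dense(coeffs: CoefficientField, alpha: float) -> np.ndarray:
    """Explicitly assemble A = D + alpha*L as a dense (H*W, H*W) matrix.

    Test-suite oracle only: reflected out-of-bounds neighbours fold into the
    diagonal, exactly as the matrix-free operator treats them.
    """
    h, w = coeffs.s.shape
    n = h * w
    A = np.zeros((n, n))
    fields = ((coeffs.c1, 0, -1), (coeffs.c2, 0, 1),
              (coeffs.c3, -1, 0), (coeffs.c4, 1, 0))
    for y in range(h):
        for x in range(w):
            p = y * w + x
            A[p, p] = 1.0 + alpha * coeffs.s[y, x]
            for c, dy, dx in fields:
                ny, nx = y + dy, x + dx
                if 0 <= ny < h and 0 <= nx < w:
                    A[p, ny * w + nx] -= alpha * c[y, x]
                else:
                    A[p, p] -= alpha * c[y, x]  # reflected neighbour
    return A


def make_rad_system(seed: int, h: int, w: int, alpha: float):
    """A seeded random diffusion system: (coefficients, alpha, rhs grid)."""
    rng = np.random.default_rng(seed)
    img = Image2D(rng.uniform(0.0, 4095.0, (h, w)))
    coeffs = compute_coefficients(img, DiffusionParams(alpha_diff=alpha))
    return coeffs, alpha, img.pixels


@pytest.fixture(scope="session")
def standard_phantom():
    """The frozen 256x256 chest-like phantom with its ground-truth masks."""
    return make_standard_phantom()


@pytest.fixture
def dense_assembler():
    return assemble_dense


@pytest.fixture
def rad_system_factory():
    return make_rad_system
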