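"""Diffusivity coefficients, the implicit operator, and the three smoothers."""

import numpy as np
import pytest

from radusm.diffusion import (
    DiffusionParams,
    apply_operator,
    compute_coefficients,
    gaussian_smooth,
    perona_malik_smooth,
    rad_smooth,
)
from radusm.exceptions import (
    ConvergenceError,
    DimensionError,
    ParameterError,
    StabilityError,
)
from radusm.image import Image2D
from radusm.synthetic import PhantomSpec, make_phantom

from conftest import make_rad_system


def random_image(seed, h=8, w=8, lo=0.0, hi=4095.0):
    return Image2D(np.random.default_rng(seed).uniform(lo, hi, (h, w)))


class TestDiffusionParams:
    @pytest.mark.parametrize(
        "kwargs",
        [dict(alpha_diff=-0.1), dict(beta=0), dict(beta=1.5), dict(grad_eps=0.0),
         dict(outer_iters=0), dict(solver_tol=0.0), dict(solver_tol=1.5)],
    )
    def test_invalid_parameters_are_refused(self, kwargs):
        with pytest.raises(ParameterError):
            DiffusionParams(**kwargs)


class TestCoefficients:
    def test_constant_image_gives_floor_coefficients(self):
        c = compute_coefficients(Image2D(np.full((6, 7), 1234.0)), DiffusionParams())
        for grid in (c.c1, c.c2, c.c3, c.c4):
            assert np.all(grid == 0.001)
        np.testing.assert_array_equal(c.s, np.full((6, 7), 4 * 0.001))

    def test_vertical_step_west_coefficient(self):
        # Columns x<2 at 0, x>=2 at 100: the pixel just right of the step sees
        # a pure 100-intensity jump to its west, so c1 = sqrt(100^2) + 0.001.
        px = np.zeros((8, 8))
        px[:, 2:] = 100.0
        c = compute_coefficients(Image2D(px), DiffusionParams())
        assert c.c1[4, 2] == pytest.approx(100.001, abs=1e-12)

    def test_adjacency_symmetry_is_exact(self):
        c = compute_coefficients(random_image(3, 12, 10), DiffusionParams())
        np.testing.assert_array_equal(c.c1[:, 1:], c.c2[:, :-1])
        np.testing.assert_array_equal(c.c3[1:, :], c.c4[:-1, :])

    @pytest.mark.parametrize("beta", [1, 2, 3])
    def test_coefficients_bounded_below_by_floor_and_sum_exact(self, beta):
        params = DiffusionParams(beta=beta)
        c = compute_coefficients(random_image(4), params)
        floor = params.grad_eps**beta
        for grid in (c.c1, c.c2, c.c3, c.c4):
            assert np.all(grid >= floor)
        np.testing.assert_array_equal(c.s, c.c1 + c.c2 + c.c3 + c.c4)


class TestApplyOperator:
    def test_alpha_zero_is_identity(self):
        img = random_image(5)
        c = compute_coefficients(img, DiffusionParams())
        v = random_image(6).pixels
        np.testing.assert_array_equal(apply_operator(c, 0.0, v), v)

    def test_constant_grid_is_fixed_under_L(self):
        c = compute_coefficients(random_image(7), DiffusionParams())
        v = np.full((8, 8), 42.0)
        np.testing.assert_allclose(apply_operator(c, 0.5, v), v, rtol=0, atol=1e-10)

    @pytest.mark.parametrize("h,w", [(4, 4), (5, 7), (8, 8)])
    def test_matches_dense_assembly(self, h, w, dense_assembler):
        coeffs, alpha, _ = make_rad_system(h * w, h, w, 0.05)
        A = dense_assembler(coeffs, alpha)
        v = np.random.default_rng(h + w).uniform(-10, 10, (h, w))
        np.testing.assert_allclose(
            apply_operator(coeffs, alpha, v).ravel(), A @ v.ravel(),
            rtol=1e-13, atol=1e-9)

    def test_shape_mismatch_is_refused(self):
        c = compute_coefficients(random_image(8), DiffusionParams())
        with pytest.raises(DimensionError):
            apply_operator(c, 0.1, np.zeros((5, 5)))


class TestRadSmooth:
    def test_alpha_zero_returns_input_exactly(self):
        img = random_image(9)
        out = rad_smooth(img, DiffusionParams(alpha_diff=0.0))
        np.testing.assert_array_equal(out.pixels, img.pixels)

    def test_constant_image_is_a_fixed_point(self):
        img = Image2D(np.full((10, 10), 777.0))
        out = rad_smooth(img, DiffusionParams())
        np.testing.assert_allclose(out.pixels, img.pixels, rtol=0, atol=1e-6)

    @pytest.mark.parametrize("outer_iters", [1, 3])
    def test_matches_dense_direct_solve(self, outer_iters, dense_assembler):
        img = random_image(10)
        params = DiffusionParams(alpha_diff=0.02, outer_iters=outer_iters,
                                 solver_tol=1e-12)
        out = rad_smooth(img, params)
        # Replay the lagged-diffusivity fixed point with dense direct solves.
        expected = img.pixels
        for _ in range(outer_iters):
            c = compute_coefficients(Image2D(expected), params)
            A = dense_assembler(c, params.alpha_diff)
            expected = np.linalg.solve(A, img.pixels.ravel()).reshape(8, 8)
        rel = np.linalg.norm(out.pixels - expected) / np.linalg.norm(expected)
        assert rel <= 1e-6

    def test_mean_is_conserved(self):
        img = random_image(11, 16, 16)
        out = rad_smooth(img, DiffusionParams(alpha_diff=0.2))
        assert abs(out.pixels.mean() - img.pixels.mean()) <= 1e-8 * img.pixels.mean()

    def test_maximum_principle(self):
        img = random_image(12, 16, 16)
        out = rad_smooth(img, DiffusionParams(alpha_diff=0.2))
        span = img.pixels.max() - img.pixels.min()
        assert out.pixels.min() >= img.pixels.min() - 1e-6 * span
        assert out.pixels.max() <= img.pixels.max() + 1e-6 * span

    def test_smoothing_distance_nondecreasing_in_alpha(self):
        spec = PhantomSpec(height=64, width=64, tubes=(), seed=5)
        img, _, _ = make_phantom(spec)
        dists = [
            np.linalg.norm(rad_smooth(img, DiffusionParams(alpha_diff=a)).pixels
                           - img.pixels)
            for a in (0.001, 0.02, 0.2)
        ]
        assert dists[0] <= dists[1] <= dists[2]

    def test_solver_budget_exhaustion_raises_with_history(self):
        img = random_image(13, 16, 16)
        params = DiffusionParams(alpha_diff=0.2, solver_tol=1e-12, solver_maxiter=2)
        with pytest.raises(ConvergenceError) as exc:
            rad_smooth(img, params)
        assert len(exc.value.residual_history) >= 1


class TestGaussianSmooth:
    def test_constant_image_unchanged(self):
        img = Image2D(np.full((20, 20), 500.0))
        np.testing.assert_allclose(gaussian_smooth(img, 15).pixels, img.pixels,
                                   rtol=0, atol=1e-9)

    def test_central_impulse_reproduces_kernel(self):
        n, ks = 41, 15
        px = np.zeros((n, n))
        px[n // 2, n // 2] = 1.0
        out = gaussian_smooth(Image2D(px), ks).pixels
        o = np.arange(ks) - ks // 2
        k1 = np.exp(-(o**2) / (2 * (ks / 6.0) ** 2))
        k1 /= k1.sum()
        kernel = np.outer(k1, k1)
        lo, hi = n // 2 - ks // 2, n // 2 + ks // 2 + 1
        np.testing.assert_allclose(out[lo:hi, lo:hi], kernel, rtol=0, atol=1e-14)
        assert np.all(out[: lo, :] == 0)

    def test_mean_preserved_by_kernel_normalization(self):
        img = random_image(14, 32, 32)
        out = gaussian_smooth(img, 19)
        assert abs(out.pixels.mean() - img.pixels.mean()) <= 1e-10 * img.pixels.mean()

    @pytest.mark.parametrize("ks", [4, 2, 1])
    def test_even_or_tiny_kernel_refused(self, ks):
        with pytest.raises(ParameterError):
            gaussian_smooth(random_image(15), ks)


class TestPeronaMalik:
    def test_constant_image_unchanged(self):
        img = Image2D(np.full((16, 16), 900.0))
        out = perona_malik_smooth(img, 40.0, 0.2, 10)
        np.testing.assert_allclose(out.pixels, img.pixels, rtol=0, atol=1e-9)

    def test_mean_conserved_by_divergence_form(self):
        img = random_image(16, 32, 32)
        out = perona_malik_smooth(img, 40.0, 0.25, 30)
        assert abs(out.pixels.mean() - img.pixels.mean()) <= 1e-8 * img.pixels.mean()

    def test_unstable_step_refused(self):
        with pytest.raises(StabilityError):
            perona_malik_smooth(random_image(17), 40.0, 0.3, 5)
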