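"""Loss identities, Laplacian behavior, and finite-difference gradient checks."""

import numpy as np
import pytest

from segae.autograd import Tensor
from segae.loss import (
    LAPLACE_KERNEL,
    LossConfig,
    activity_regularizer,
    cosine_proximity,
    laplacian_filter,
    reconstruction_loss,
    total_loss,
)


class TestCosineProximity:
    def test_self_similarity(self, rng):
        y = rng.standard_normal(20)
        assert cosine_proximity(y, y) == pytest.approx(1.0)

    def test_orthogonal(self):
        assert cosine_proximity([1.0, 0.0], [0.0, 1.0]) == pytest.approx(0.0)

    def test_scale_invariance(self, rng):
        y = rng.standard_normal(50)
        yh = rng.standard_normal(50)
        for a in (0.01, 3.0, 1e4):
            assert cosine_proximity(a * y, yh) == pytest.approx(
                cosine_proximity(y, yh), abs=1e-12
            )

    def test_zero_vector_guarded(self):
        z = np.zeros(10)
        v = np.ones(10)
        assert abs(cosine_proximity(z, v)) < 1e-3
        assert abs(cosine_proximity(z, z)) < 1e-3


class TestLaplacianFilter:
    def test_kernel_stencil(self):
        assert LAPLACE_KERNEL.sum() == 0
        assert LAPLACE_KERNEL[1, 1, 1] == -6
        # symmetric under axis permutation
        for perm in [(1, 0, 2), (2, 1, 0), (0, 2, 1)]:
            assert np.array_equal(LAPLACE_KERNEL, LAPLACE_KERNEL.transpose(perm))

    def test_annihilates_constant(self):
        out = laplacian_filter(np.full((6, 6, 6), 3.7))
        assert np.abs(out[1:-1, 1:-1, 1:-1]).max() < 1e-12

    def test_annihilates_affine(self):
        i, j, k = np.mgrid[0:7, 0:7, 0:7]
        out = laplacian_filter(2.0 * i - 3.0 * j + 0.5 * k + 1.0)
        assert np.abs(out[1:-1, 1:-1, 1:-1]).max() < 1e-12

    def test_impulse_response(self):
        v = np.zeros((5, 5, 5))
        v[2, 2, 2] = 1.0
        out = laplacian_filter(v)
        assert np.allclose(out[1:4, 1:4, 1:4], LAPLACE_KERNEL)

    def test_interior_six_neighbor_identity(self, rng):
        v = rng.standard_normal((6, 6, 6))
        out = laplacian_filter(v)
        i, j, k = 3, 2, 3
        expected = (
            v[i - 1, j, k] + v[i + 1, j, k] + v[i, j - 1, k] + v[i, j + 1, k]
            + v[i, j, k - 1] + v[i, j, k + 1] - 6 * v[i, j, k]
        )
        assert out[i, j, k] == pytest.approx(expected)

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            laplacian_filter(np.zeros((2, 5, 5)))


class TestReconstructionLoss:
    def test_perfect_reconstruction_is_minus_two(self, rng):
        y = rng.standard_normal((2, 6, 6, 6))
        assert reconstruction_loss(y, y) == pytest.approx(-2.0)

    def test_positive_rescaling_invariance(self, rng):
        y = rng.random((3, 6, 6, 6))
        yh = rng.random((3, 6, 6, 6))
        base = reconstruction_loss(y, yh)
        scaled = yh * np.array([0.1, 7.0, 42.0]).reshape(3, 1, 1, 1)
        assert reconstruction_loss(y, scaled) == pytest.approx(base, abs=1e-6)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            reconstruction_loss(np.zeros((2, 6, 6, 6)), np.zeros((3, 6, 6, 6)))

    def test_laplacian_term_robust_to_smooth_field(self, rng):
        """A low-frequency perturbation hurts the intensity term more than
        the Laplacian term (the rationale for filtering)."""
        from scipy.ndimage import gaussian_filter

        y = rng.random((16, 16, 16))
        field = gaussian_filter(rng.standard_normal((16, 16, 16)), 6)
        field = 0.8 * field / np.abs(field).max()
        yh = y + field
        f_int = cosine_proximity(y, yh)
        f_lap = cosine_proximity(laplacian_filter(y), laplacian_filter(yh))
        assert 1 - f_int > 1 - f_lap

    def test_bounds(self, rng):
        y = rng.standard_normal((2, 5, 5, 5))
        yh = rng.standard_normal((2, 5, 5, 5))
        assert -2.0 <= reconstruction_loss(y, yh) <= 2.0


class TestActivityRegularizer:
    def test_disjoint_maps_give_alpha(self):
        maps = np.zeros((3, 4, 4, 4))
        maps[0, :2], maps[1, 2], maps[2, 3] = 1.0, 1.0, 1.0
        alpha = 0.0075
        assert activity_regularizer(maps, alpha) == pytest.approx(alpha)

    def test_identical_maps_give_alpha_m(self, rng):
        m = 4
        base = rng.random((4, 4, 4)) + 0.1
        maps = np.stack([base] * m)
        alpha = 0.02
        assert activity_regularizer(maps, alpha) == pytest.approx(alpha * m)

    def test_alpha_zero(self, rng):
        maps = rng.random((3, 4, 4, 4))
        assert activity_regularizer(maps, 0.0) == 0.0

    def test_monotone_in_overlap(self):
        """Sliding one blob across another increases the off-diagonal term."""
        n = 24
        x = np.arange(n)
        vals = []
        for shift in (12, 8, 4, 0):
            a = np.exp(-0.5 * ((x - 8) / 2.0) ** 2)
            b = np.exp(-0.5 * ((x - 8 - shift) / 2.0) ** 2)
            maps = np.stack([np.tile(a, (4, 4, 1)), np.tile(b, (4, 4, 1))])
            vals.append(activity_regularizer(maps, 1.0))
        assert all(v2 > v1 for v1, v2 in zip(vals, vals[1:]))


class TestTotalLoss:
    def test_perfect_case_sum(self, rng):
        y = rng.random((2, 6, 6, 6)) + 0.1
        maps = np.zeros((3, 6, 6, 6))
        maps[0, :2], maps[1, 2:4], maps[2, 4:] = 1.0, 1.0, 1.0
        cfg = LossConfig(alpha=0.0075)
        assert total_loss(y, y, maps, cfg) == pytest.approx(-2.0 + 0.0075)

    def test_alpha_zero_reduces_to_reconstruction(self, rng):
        y = rng.random((2, 6, 6, 6))
        yh = rng.random((2, 6, 6, 6))
        maps = rng.random((3, 6, 6, 6))
        cfg = LossConfig(alpha=0.0)
        assert total_loss(y, yh, maps, cfg) == pytest.approx(reconstruction_loss(y, yh))

    def test_per_channel_scale_invariance(self, rng):
        y = rng.random((3, 6, 6, 6))
        yh = rng.random((3, 6, 6, 6))
        maps = rng.random((4, 6, 6, 6))
        cfg = LossConfig()
        d = np.array([0.5, 2.0, 9.0]).reshape(3, 1, 1, 1)
        assert total_loss(y, yh * d, maps, cfg) == pytest.approx(
            total_loss(y, yh, maps, cfg), abs=1e-6
        )


def _finite_difference_grad(fn, x, eps=1e-6):
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        xp = x.copy()
        xp[idx] += eps
        xm = x.copy()
        xm[idx] -= eps
        g[idx] = (fn(xp) - fn(xm)) / (2 * eps)
    return g


def _relative_error(a, b):
    denom = max(np.abs(a).max(), np.abs(b).max(), 1e-12)
    return np.abs(a - b).max() / denom


class TestGradients:
    """Analytic gradients vs central finite differences on random 5^3 patches."""

    def test_reconstruction_loss_gradient(self, rng):
        y = rng.random((2, 5, 5, 5))
        yh0 = rng.random((2, 5, 5, 5)) + 0.1

        t = Tensor(yh0.copy(), requires_grad=True)
        loss = reconstruction_loss(Tensor(y), t)
        loss.backward()
        num = _finite_difference_grad(lambda v: reconstruction_loss(y, v), yh0)
        assert _relative_error(t.grad, num) < 1e-4

    def test_activity_regularizer_gradient(self, rng):
        s0 = rng.random((3, 5, 5, 5)) + 0.05
        t = Tensor(s0.copy(), requires_grad=True)
        loss = activity_regularizer(t, alpha=0.02)
        loss.backward()
        num = _finite_difference_grad(lambda v: activity_regularizer(v, alpha=0.02), s0)
        assert _relative_error(t.grad, num) < 1e-4

    def test_total_loss_gradient_wrt_reconstruction(self, rng):
        y = rng.random((2, 5, 5, 5))
        yh0 = rng.random((2, 5, 5, 5)) + 0.1
        s = rng.random((3, 5, 5, 5))
        cfg = LossConfig(alpha=0.0075)
        t = Tensor(yh0.copy(), requires_grad=True)
        loss = total_loss(Tensor(y), t, Tensor(s), cfg)
        loss.backward()
        num = _finite_difference_grad(lambda v: total_loss(y, v, s, cfg), yh0)
        assert _relative_error(t.grad, num) < 1e-4

    def test_laplacian_term_gradient(self, rng):
        y = rng.random((5, 5, 5))
        x0 = rng.random((5, 5, 5))

        def fn(v):
            return cosine_proximity(laplacian_filter(y), laplacian_filter(v))

        t = Tensor(x0.copy(), requires_grad=True)
        loss = cosine_proximity(laplacian_filter(Tensor(y)), laplacian_filter(t))
        loss.backward()
        num = _finite_difference_grad(fn, x0)
        assert _relative_error(t.grad, num) < 1e-4
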