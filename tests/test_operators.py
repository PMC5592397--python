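"""Transforms, adjoints, and proximal operators against independent oracles."""

import numpy as np
import pytest

from dcecs import operators as ops

from oracles import (
    l1_analysis_prox,
    nuclear_prox_bruteforce,
    scalar_l1_prox,
    tgv_prox_bruteforce,
    tv_prox_bruteforce,
)


def crandn(rng, shape):
    return rng.standard_normal(shape) + 1j * rng.standard_normal(shape)


# ---------------------------------------------------------------------------
# soft threshold / box projection
# ---------------------------------------------------------------------------

class TestSoftThreshold:
    def test_closed_form_complex(self):
        out = ops.soft_threshold(np.array([3 + 4j]), 1.0)
        assert np.allclose(out, [2.4 + 3.2j])

    def test_zero_tau_is_identity(self, rng):
        u = crandn(rng, 10)
        assert np.allclose(ops.soft_threshold(u, 0.0), u)

    def test_full_shrinkage(self, rng):
        u = crandn(rng, 10)
        assert np.all(ops.soft_threshold(u, np.abs(u).max() + 0.1) == 0)

    def test_negative_tau_rejected(self):
        with pytest.raises(ValueError):
            ops.soft_threshold(np.ones(3), -0.5)

    def test_matches_scalar_numeric_minimizer(self, rng):
        u = crandn(rng, 20)
        tau = 0.7
        out = ops.soft_threshold(u, tau)
        for ui, oi in zip(u, out):
            m = scalar_l1_prox(abs(ui), tau)
            assert abs(oi - m * np.exp(1j * np.angle(ui))) < 1e-6


class TestProjectBox:
    @pytest.mark.parametrize("x,expected", [(0.5, 0.5), (-2.0, 0.0), (3.0, 1.0)])
    def test_three_cases(self, x, expected):
        assert ops.project_box(np.array([x]), 0.0, 1.0)[0] == expected

    def test_invalid_bounds(self):
        with pytest.raises(ValueError):
            ops.project_box(np.zeros(3), 1.0, 0.0)


# ---------------------------------------------------------------------------
# linear operator pairs
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("make_op", [ops.temporal_dft_op, ops.temporal_haar_op],
                         ids=["dft", "haar"])
@pytest.mark.parametrize("d", [5, 8, 16, 105])
def test_adjoint_and_unitarity(make_op, d, rng):
    op = make_op(d)
    for _ in range(20):
        x, y = crandn(rng, (3, d)), crandn(rng, (3, d))
        lhs = np.vdot(y, op.forward(x))
        rhs = np.vdot(op.adjoint(y), x)
        assert abs(lhs - rhs) <= 1e-10 * np.linalg.norm(x) * np.linalg.norm(y)
        assert abs(np.linalg.norm(op.forward(x)) - np.linalg.norm(x)) < 1e-10
        assert np.allclose(op.adjoint(op.forward(x)), x, atol=1e-12)


def test_haar_matches_pywt_on_power_of_two(rng):
    """For power-of-two lengths the transform is the standard orthonormal Haar."""
    pywt = pytest.importorskip("pywt")
    for d in (8, 16):
        x = rng.standard_normal(d)
        mine = ops.temporal_haar_op(d).forward(x)
        coeffs = pywt.wavedec(x, "haar", mode="periodization")
        ref = np.concatenate(coeffs)
        assert np.allclose(np.sort(np.abs(mine)), np.sort(np.abs(ref)), atol=1e-10)


def test_haar_sparsifies_piecewise_constant():
    x = np.concatenate([np.full(8, 2.0), np.full(8, 5.0)])
    coeffs = ops.temporal_haar_op(16).forward(x)
    assert np.sum(np.abs(coeffs) > 1e-8) <= 2  # one scale coeff + one jump detail


def test_dft_sparsifies_periodic():
    d = 16
    t = np.arange(d)
    x = 1.5 + np.cos(2 * np.pi * 2 * t / d)
    coeffs = ops.temporal_dft_op(d).forward(x)
    assert np.sum(np.abs(coeffs) > 1e-8) == 3  # DC plus the +/- harmonic


class TestTemporalDiff:
    def test_constant_gives_zero(self):
        assert np.all(ops.temporal_diff(np.ones((4, 6))) == 0)

    def test_single_jump(self):
        x = np.zeros((1, 5))
        x[0, 3:] = 2.5
        y = ops.temporal_diff(x)
        assert y[0, 2] == 2.5
        assert np.count_nonzero(y) == 1

    def test_adjoint_identity(self, rng):
        for _ in range(20):
            x, y = crandn(rng, (4, 9)), crandn(rng, (4, 9))
            lhs = np.vdot(y, ops.temporal_diff(x))
            rhs = np.vdot(ops.temporal_diff_adjoint(y), x)
            assert abs(lhs - rhs) <= 1e-10 * np.linalg.norm(x) * np.linalg.norm(y)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            ops.temporal_diff(np.ones((3, 1)))


# ---------------------------------------------------------------------------
# prox of l1 o unitary
# ---------------------------------------------------------------------------

class TestProxL1Unitary:
    def test_requires_unitary(self, rng):
        bad = ops.LinearOperatorPair(lambda x: 2 * x, lambda y: 2 * y, False)
        with pytest.raises(ValueError):
            ops.prox_l1_unitary(bad, crandn(rng, 4), 0.1)

    def test_zero_tau_identity(self, rng):
        x = crandn(rng, (2, 6))
        out = ops.prox_l1_unitary(ops.temporal_dft_op(6), x, 0.0)
        assert np.allclose(out, x, atol=1e-12)

    def test_constant_voxel_stays_constant(self):
        x = np.full((1, 8), 3.0 + 0j)
        out = ops.prox_l1_unitary(ops.temporal_dft_op(8), x, 0.05)
        assert np.allclose(out, out[..., :1])  # still constant in time
        assert np.abs(out).max() < 3.0  # DC coefficient shrunk slightly

    @pytest.mark.parametrize("make_op", [ops.temporal_dft_op, ops.temporal_haar_op],
                             ids=["dft", "haar"])
    def test_matches_coefficient_domain_numeric_minimizer(self, make_op, rng):
        """Per-coefficient scalar numeric minimization is an independent oracle
        because the unitary change of variables makes the objective separable."""
        d = 6
        op = make_op(d)
        for _ in range(10):
            x = crandn(rng, d)
            tau = float(rng.uniform(0.05, 1.0))
            out = ops.prox_l1_unitary(op, x, tau)
            c = op.forward(x)
            expected_c = np.array([
                scalar_l1_prox(abs(ci), tau) * np.exp(1j * np.angle(ci)) for ci in c
            ])
            assert np.allclose(out, op.adjoint(expected_c), atol=1e-7)

    def test_real_haar_matches_full_vector_bruteforce(self, rng):
        d = 6
        w = ops.haar_matrix(d)
        for _ in range(5):
            x = rng.standard_normal(d)
            tau = float(rng.uniform(0.1, 0.8))
            out = ops.prox_l1_unitary(ops.temporal_haar_op(d), x, tau)
            ref = l1_analysis_prox(w, x, tau)
            assert np.allclose(out.real, ref, atol=1e-5)
            assert np.abs(out.imag).max() < 1e-12


# ---------------------------------------------------------------------------
# singular value thresholding
# ---------------------------------------------------------------------------

class TestProxNuclear:
    def test_rank_one_closed_form(self, rng):
        u = rng.standard_normal(6)
        v = rng.standard_normal(4)
        u /= np.linalg.norm(u)
        v /= np.linalg.norm(v)
        s = 3.0
        out = ops.prox_nuclear(s * np.outer(u, v), 1.0)
        assert np.allclose(out, (s - 1.0) * np.outer(u, v), atol=1e-10)

    def test_large_tau_zeroes(self, rng):
        x = rng.standard_normal((5, 3))
        smax = np.linalg.svd(x, compute_uv=False)[0]
        assert np.allclose(ops.prox_nuclear(x, smax + 0.1), 0.0)

    def test_zero_tau_identity(self, rng):
        x = rng.standard_normal((5, 3))
        assert np.allclose(ops.prox_nuclear(x, 0.0), x, atol=1e-12)

    def test_matches_derivative_free_bruteforce(self, rng):
        for _ in range(3):
            x = rng.standard_normal((4, 2))
            tau = float(rng.uniform(0.2, 0.8))
            out = ops.prox_nuclear(x, tau)
            ref = nuclear_prox_bruteforce(x, tau)
            assert np.abs(out - ref).max() < 1e-5


# ---------------------------------------------------------------------------
# TV / TGV denoisers
# ---------------------------------------------------------------------------

class TestTVDenoise:
    def test_zero_weight_identity(self, rng):
        x = crandn(rng, (3, 7))
        assert np.allclose(ops.tv_denoise(x, 0.0), x)

    def test_two_frame_closed_form(self):
        """With one difference, the pair's gap shrinks by 2*weight and the
        mean is preserved (1-D TV prox closed form)."""
        x = np.array([0.3, 1.1])
        w = 0.15
        z = ops.tv_denoise(x, w, n_iter=4000, sigma=0.45, tau_step=0.45)
        assert abs((z[1] - z[0]) - (0.8 - 2 * w)) < 1e-6
        assert abs(z.mean() - x.mean()) < 1e-6

    def test_matches_bruteforce_on_short_series(self, rng):
        for _ in range(5):
            x = rng.standard_normal(5)
            w = float(rng.uniform(0.1, 0.6))
            z = ops.tv_denoise(x, w, n_iter=20000, sigma=0.45, tau_step=0.45)
            ref = tv_prox_bruteforce(x, w)
            assert np.abs(z - ref).max() < 1e-5

    def test_invalid_steps_rejected(self):
        with pytest.raises(ValueError):
            ops.tv_denoise(np.ones((2, 4)), 0.1, sigma=1.0, tau_step=1.0)


class TestTGVDenoise:
    def test_constant_unchanged(self):
        x = np.full((2, 6), 1.7)
        z = ops.tgv_denoise(x, 0.2, 0.4, n_iter=2000, sigma=0.25, tau_step=0.25)
        assert np.abs(z - x).max() < 1e-8

    def test_ramp_preserved_tv_flattens(self):
        """Second-order TGV leaves affine time courses untouched at weights
        where TV visibly flattens them."""
        ramp = np.linspace(0.0, 1.0, 6)
        zt = ops.tgv_denoise(ramp, 0.05, 0.1, n_iter=8000, sigma=0.25, tau_step=0.25)
        ztv = ops.tv_denoise(ramp, 0.05, n_iter=8000, sigma=0.45, tau_step=0.45)
        assert np.abs(zt - ramp).max() < 1e-3
        assert np.abs(ztv - ramp).max() > 0.04

    def test_reduces_to_tv_with_anchored_v(self, rng):
        """alpha0 -> inf forces v -> 0 under the Dirichlet convention, so the
        denoiser must coincide with TV."""
        x = rng.standard_normal(8)
        a1 = 0.3
        tv = ops.tv_denoise(x, a1, n_iter=20000, sigma=0.45, tau_step=0.45)
        tg = ops.tgv_denoise(x, a1, 1e6 * a1, n_iter=20000, sigma=0.25,
                             tau_step=0.25, v_boundary="dirichlet")
        assert np.abs(tg - tv).max() < 1e-4

    @pytest.mark.parametrize("v_boundary", ["neumann", "dirichlet"])
    def test_matches_bruteforce_on_short_series(self, v_boundary, rng):
        for _ in range(4):
            x = rng.standard_normal(6)
            a1 = float(rng.uniform(0.1, 0.5))
            a0 = 2.0 * a1
            z = ops.tgv_denoise(x, a1, a0, n_iter=20000, sigma=0.25,
                                tau_step=0.25, v_boundary=v_boundary)
            ref = tgv_prox_bruteforce(x, a1, a0, v_boundary=v_boundary)
            assert np.abs(z - ref).max() < 1e-5

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            ops.tgv_denoise(np.ones((2, 4)), 0.0, 0.1)
        with pytest.raises(ValueError):
            ops.tgv_denoise(np.ones((2, 4)), 0.1, 0.2, v_boundary="periodic")


@pytest.mark.parametrize("prox", [
    lambda a: ops.soft_threshold(a, 0.3),
    lambda a: ops.prox_l1_unitary(ops.temporal_dft_op(8), a, 0.3),
    lambda a: ops.prox_nuclear(a.reshape(4, 8), 0.3).reshape(a.shape),
    lambda a: ops.tv_denoise(a.reshape(4, 8), 0.3, n_iter=3000, sigma=0.45, tau_step=0.45).reshape(a.shape),
    lambda a: ops.tgv_denoise(a.reshape(4, 8), 0.3, 0.6, n_iter=3000, sigma=0.25, tau_step=0.25).reshape(a.shape),
], ids=["soft", "l1_dft", "nuclear", "tv", "tgv"])
def test_prox_nonexpansive(prox, rng):
    """Proximal maps of convex functions are 1-Lipschitz."""
    for _ in range(5):
        a = crandn(rng, 32)
        b = crandn(rng, 32)
        pa, pb = prox(a), prox(b)
        assert np.linalg.norm(pa - pb) <= np.linalg.norm(a - b) + 1e-6


def test_self_test_passes(capsys):
    assert ops.self_test(seed=3)
    assert "PASS" in capsys.readouterr().out
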