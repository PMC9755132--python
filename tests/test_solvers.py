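"""Reconstruction solvers: closed forms, subproblem cross-validation,
ADMM fixed points and regularisation behaviour."""

import numpy as np
import pytest

from pnpqsm import (
    ADMMParams,
    add_noise_back,
    build_dipole_kernel,
    forward_field,
    l2_closed_form,
    pnp_admm,
    tv_admm,
)
from pnpqsm.denoise import DenoiserSpec
from pnpqsm.phantom import Inclusion, NoiseSpec, PhantomSpec, make_phantom, simulate_observation
from pnpqsm.solvers import chi_subproblem, soft_shrink
from pnpqsm.volume import VolumeGrid


@pytest.fixture(scope="module")
def sphere_obs():
    n = 48
    kernel = build_dipole_kernel((n,) * 3)
    chi, _, _ = make_phantom(
        PhantomSpec(shape=(n,) * 3, inclusions=[Inclusion("sphere", (24,) * 3, 10.0, 0.1, 1)])
    )
    chi.mask = None
    noisy = simulate_observation(chi, kernel, NoiseSpec(sigma=0.002, seed=1))
    return chi, noisy, kernel


class TestL2ClosedForm:
    def test_zero_field(self, kernel16):
        out = l2_closed_form(VolumeGrid(np.zeros((16, 16, 16))), kernel16, 0.1)
        np.testing.assert_array_equal(out.data, 0.0)

    def test_single_frequency_identity_mode(self, kernel16):
        # a pure cosine at one FFT bin passes through as D0/(D0^2+alpha)
        n = 16
        idx = (2, 3, 1)
        spec = np.zeros((n,) * 3, dtype=complex)
        spec[idx] = 1.0
        spec[tuple((-np.array(idx)) % n)] = 1.0  # keep the volume real
        phi = VolumeGrid(np.fft.ifftn(spec).real)
        alpha = 0.05
        d0 = kernel16.values[idx]
        out = l2_closed_form(phi, kernel16, alpha, mode="identity")
        out_spec = np.fft.fftn(out.data)
        assert out_spec[idx] == pytest.approx(d0 / (d0**2 + alpha), rel=1e-10)

    def test_gradient_mode_lower_hfen_than_identity(self, sphere_obs):
        from pnpqsm.metrics import hfen

        chi, noisy, kernel = sphere_obs
        grad = l2_closed_form(noisy, kernel, alpha=5e-3, mode="gradient")
        ident = l2_closed_form(noisy, kernel, alpha=5e-3, mode="identity")
        assert hfen(grad, chi) < hfen(ident, chi)

    def test_nonpositive_alpha_rejected(self, kernel16):
        with pytest.raises(ValueError):
            l2_closed_form(VolumeGrid(np.zeros((16, 16, 16))), kernel16, 0.0)


class TestChiSubproblem:
    def test_all_zero_inputs(self, kernel16):
        z = np.zeros((16, 16, 16))
        params = ADMMParams(mu=1.0, beta=1.0)
        out = chi_subproblem(z, z, z, kernel16, params)
        np.testing.assert_allclose(out, 0.0, atol=1e-14)

    def test_mu_zero_limit_returns_v_minus_u(self, kernel16, rng):
        # as mu -> 0 the proximal term dominates and chi -> v - u
        v = rng.normal(size=(16, 16, 16))
        u = rng.normal(size=(16, 16, 16)) * 0.1
        phi = rng.normal(size=(16, 16, 16))
        params = ADMMParams(mu=1e-14, beta=1.0)
        out = chi_subproblem(v, u, phi, kernel16, params)
        np.testing.assert_allclose(out, v - u, atol=1e-12)

    def test_cg_matches_closed_form_with_unit_mask(self, kernel48, rng):
        n = 48
        v = rng.normal(size=(n,) * 3)
        u = 0.1 * rng.normal(size=(n,) * 3)
        phi = rng.normal(size=(n,) * 3)
        closed = chi_subproblem(v, u, phi, kernel48, ADMMParams(mu=1.0, beta=1.0))
        params = ADMMParams(
            mu=1.0, beta=1.0, fidelity_weight_M=np.ones((n,) * 3),
            cg_iters=400, cg_tol=1e-12,
        )
        viacg = chi_subproblem(v, u, phi, kernel48, params)
        rel = np.linalg.norm(viacg - closed) / np.linalg.norm(closed)
        assert rel < 1e-6

    def test_cg_with_binary_mask_stays_finite(self, kernel48, rng):
        n = 48
        mask = np.zeros((n,) * 3)
        mask[10:38, 10:38, 10:38] = 1
        params = ADMMParams(mu=10.0, beta=1.0, fidelity_weight_M=mask, cg_iters=50)
        out = chi_subproblem(
            rng.normal(size=(n,) * 3), np.zeros((n,) * 3),
            rng.normal(size=(n,) * 3), kernel48, params,
        )
        assert np.all(np.isfinite(out))


class TestPnpAdmm:
    def test_exact_recovery_identity_denoiser(self, kernel48, rng):
        # noiseless data from a cone-free spectrum is recovered exactly
        raw = rng.normal(size=(48,) * 3)
        spec = np.fft.fftn(raw)
        spec[np.abs(kernel48.values) < 0.15] = 0
        chi = VolumeGrid(np.fft.ifftn(spec).real)
        phi = forward_field(chi, kernel48)
        params = ADMMParams(
            mu=200.0, beta=1.0, max_iters=40, rel_tol=0.0,
            denoiser=DenoiserSpec(name="identity"),
        )
        rec, state = pnp_admm(phi, kernel48, params)
        rel = np.linalg.norm(rec.data - chi.data) / np.linalg.norm(chi.data)
        assert rel < 1e-4

    def test_zero_iterations_returns_initial(self, kernel16, rng):
        phi = VolumeGrid(rng.normal(size=(16, 16, 16)))
        params = ADMMParams(max_iters=0, denoiser=DenoiserSpec(name="identity"))
        rec, state = pnp_admm(phi, kernel16, params)
        np.testing.assert_array_equal(rec.data, 0.0)
        assert state.iteration == 0
        init = VolumeGrid(rng.normal(size=(16, 16, 16)))
        rec2, _ = pnp_admm(phi, kernel16, params, initial_chi=init)
        np.testing.assert_array_equal(rec2.data, init.data)

    def test_fixed_point_does_not_move(self, kernel16):
        # chi = v = 0, u = 0 with phi = 0 solves every subproblem exactly
        phi = VolumeGrid(np.zeros((16, 16, 16)))
        params = ADMMParams(max_iters=5, rel_tol=0.0, denoiser=DenoiserSpec(name="identity"))
        rec, state = pnp_admm(phi, kernel16, params)
        assert np.linalg.norm(rec.data) < 1e-10
        assert all(p < 1e-10 for p, _ in state.residual_history)

    def test_primal_residual_monotone_identity_denoiser(self, kernel48, rng):
        raw = rng.normal(size=(48,) * 3)
        spec = np.fft.fftn(raw)
        spec[np.abs(kernel48.values) < 0.15] = 0
        chi = VolumeGrid(np.fft.ifftn(spec).real)
        phi = forward_field(chi, kernel48)
        params = ADMMParams(
            mu=50.0, beta=1.0, max_iters=15, rel_tol=0.0,
            denoiser=DenoiserSpec(name="identity"),
        )
        _, state = pnp_admm(phi, kernel48, params)
        primal = [p for p, _ in state.residual_history]
        assert all(b <= a + 1e-12 for a, b in zip(primal[1:], primal[2:]))

    def test_determinism(self, kernel16, rng):
        phi = VolumeGrid(rng.normal(size=(16, 16, 16)) * 0.01)
        params = ADMMParams(
            mu=10.0, max_iters=4, denoiser=DenoiserSpec(name="bm4d", sigma=0.01)
        )
        a, _ = pnp_admm(phi, kernel16, params)
        b, _ = pnp_admm(phi, kernel16, params)
        np.testing.assert_array_equal(a.data, b.data)


class TestTvAdmm:
    def test_shrinkage_closed_form(self):
        g = np.array([[3.0], [4.0]])  # magnitude 5 along axis 0
        out = soft_shrink(g, 1.0)
        np.testing.assert_allclose(out, g * (4.0 / 5.0))
        np.testing.assert_allclose(soft_shrink(np.array([[2.0]]), 2.0), 0.0)

    def test_small_alpha_drives_data_residual_down(self, kernel48, rng):
        raw = rng.normal(size=(48,) * 3)
        spec = np.fft.fftn(raw)
        spec[np.abs(kernel48.values) < 0.15] = 0
        chi = VolumeGrid(np.fft.ifftn(spec).real)
        phi = forward_field(chi, kernel48)
        params = ADMMParams(mu=50.0, alpha=1e-8, beta=0.1, max_iters=40, rel_tol=0.0)
        _, state = tv_admm(phi, kernel48, params)
        data_res = [d for _, d in state.residual_history]
        assert data_res[-1] < 0.02 * np.linalg.norm(phi.data)

    def test_tv_output_flatter_than_l2(self, sphere_obs):
        chi, noisy, kernel = sphere_obs

        def tv_norm(x):
            return sum(np.abs(np.diff(x, axis=a)).sum() for a in range(3))

        l2 = l2_closed_form(noisy, kernel, alpha=5e-3)
        params = ADMMParams(mu=1.0, alpha=3e-4, beta=0.1, max_iters=40, rel_tol=1e-4)
        tvr, _ = tv_admm(noisy, kernel, params)
        assert tv_norm(tvr.data) < tv_norm(l2.data)
        from pnpqsm.metrics import rmse

        assert rmse(tvr, chi) < rmse(l2, chi)


class TestAddNoiseBack:
    def test_lambda_zero_untouched(self, kernel16, rng):
        phi = VolumeGrid(rng.normal(size=(16, 16, 16)))
        chi = VolumeGrid(rng.normal(size=(16, 16, 16)))
        out = add_noise_back(phi, chi, kernel16, 0.0)
        np.testing.assert_array_equal(out.data, phi.data)

    def test_consistent_chi_untouched(self, kernel16, rng):
        chi = VolumeGrid(rng.normal(size=(16, 16, 16)))
        phi = forward_field(chi, kernel16)
        out = add_noise_back(phi, chi, kernel16, 1.0)
        np.testing.assert_allclose(out.data, phi.data, atol=1e-12)

    def test_zero_chi_doubles_field(self, kernel16, rng):
        phi = VolumeGrid(rng.normal(size=(16, 16, 16)))
        chi = VolumeGrid(np.zeros((16, 16, 16)))
        out = add_noise_back(phi, chi, kernel16, 1.0)
        np.testing.assert_allclose(out.data, 2 * phi.data, atol=1e-12)

    def test_lambda_domain(self, kernel16):
        z = VolumeGrid(np.zeros((16, 16, 16)))
        with pytest.raises(ValueError):
            add_noise_back(z, z, kernel16, 1.5)
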