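"""Dipole-inversion solvers: closed-form L2, TV-ADMM, and plug-and-play ADMM.

All solvers minimise variants of

    mu/2 ||M (F^H D F chi - phi)||_2^2 + alpha * R(chi)

over the susceptibility map chi, given the observed local field phi and the
Fourier-domain dipole kernel D.  The Tikhonov (L2) baseline has a
closed-form Fourier solution.  QSM-TV splits on the spatial gradient and
alternates a Fourier-diagonal chi-update with isotropic soft-thresholding.
The plug-and-play solver splits chi = v with scaled dual u and replaces the
regulariser's proximal step by an arbitrary registered denoiser:

    chi <- argmin  beta/2 ||chi - v + u||^2 + mu/2 ||M(A chi - phi)||^2
    v   <- D_sigma(chi + u)
    u   <- u + (chi - v)

When the fidelity weight M is the identity the chi-update is a pointwise
Fourier division; for a mask or spatial weight it is solved by warm-started
conjugate gradients.  The optional "adding-noise-back" step remixes a
fraction lambda of the data residual into the observation before each
chi-update to counteract over-smoothing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.linalg import LinearOperator, cg

from .denoise import DenoiserSpec, denoise
from .dipole import DipoleKernel, forward_field
from .volume import VolumeGrid

logger = logging.getLogger(__name__)

__all__ = [
    "ADMMParams",
    "ADMMState",
    "l2_closed_form",
    "chi_subproblem",
    "pnp_admm",
    "tv_admm",
    "add_noise_back",
    "soft_shrink",
]


@dataclass
class ADMMParams:
    """Tunable weights and iteration controls shared by the ADMM solvers.

    ``mu`` weights data fidelity, ``alpha`` the regulariser (for TV the
    gradient-L1 weight; for PnP it sets the default denoiser strength
    sigma = sqrt(alpha/beta)), ``beta`` the splitting penalty.
    ``fidelity_weight_M`` is ``None`` (identity), a binary mask, or a spatial
    weight volume; ``tv_weight_W`` an optional edge-weight volume for TV.
    ``noise_back_lambda`` in [0, 1] enables the adding-noise-back step.
    ``sigma_decay`` geometrically shrinks the denoiser sigma per iteration
    (1.0 = fixed).
    """

    mu: float = 1.0
    alpha: float = 1e-3
    beta: float = 1.0
    max_iters: int = 50
    rel_tol: float = 1e-3
    denoiser: DenoiserSpec = field(default_factory=DenoiserSpec)
    tv_weight_W: np.ndarray | None = None
    fidelity_weight_M: np.ndarray | None = None
    noise_back_lambda: float = 0.0
    sigma_decay: float = 1.0
    cg_iters: int = 30
    cg_tol: float = 1e-6

    def __post_init__(self) -> None:
        if self.mu <= 0 or self.beta <= 0:
            raise ValueError("mu and beta must be positive")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.max_iters < 0:
            raise ValueError("max_iters must be >= 0")
        if not (0.0 <= self.noise_back_lambda <= 1.0):
            raise ValueError("noise_back_lambda must lie in [0, 1]")


@dataclass
class ADMMState:
    """Final iterates and per-iteration residual history.

    ``residual_history`` rows are (primal ||chi - v||_2,
    data ||M (A chi - phi)||_2).
    """

    chi: np.ndarray
    v: np.ndarray
    u: np.ndarray
    iteration: int
    residual_history: list[tuple[float, float]] = field(default_factory=list)


def _gradient_symbol_sq(shape, voxel_size) -> np.ndarray:
    """Sum_i |E_i(k)|^2 for forward differences with periodic boundary."""
    total = np.zeros(shape)
    for ax, (n, d) in enumerate(zip(shape, voxel_size)):
        f = np.fft.fftfreq(n)
        e2 = (2.0 * np.sin(np.pi * f)) ** 2 / d**2
        sh = [1, 1, 1]
        sh[ax] = n
        total = total + e2.reshape(sh)
    return total


def _grad(x: np.ndarray, voxel_size) -> list[np.ndarray]:
    return [
        (np.roll(x, -1, axis=ax) - x) / voxel_size[ax] for ax in range(x.ndim)
    ]


def _div(g: list[np.ndarray], voxel_size) -> np.ndarray:
    # negative adjoint of _grad (periodic backward differences)
    out = np.zeros_like(g[0])
    for ax, gi in enumerate(g):
        out += (gi - np.roll(gi, 1, axis=ax)) / voxel_size[ax]
    return out


def l2_closed_form(
    phi: VolumeGrid, kernel: DipoleKernel, alpha: float, mode: str = "gradient"
) -> VolumeGrid:
    """Tikhonov-regularised inversion with a pointwise Fourier solution.

    chi_hat = F^H [ D F(phi) / (D^2 + alpha * P) ] with P = 1 (``identity``
    mode, plain Tikhonov) or P = sum_i |E_i|^2 for the FFT-diagonal gradient
    operators (``gradient`` mode, default — penalises gradient energy).
    """
    if alpha <= 0:
        raise ValueError("alpha must be > 0 (the inversion blows up on the cone)")
    if mode not in ("identity", "gradient"):
        raise ValueError(f"mode must be 'identity' or 'gradient', got {mode!r}")
    d = kernel.values
    if mode == "identity":
        p = 1.0
    else:
        p = _gradient_symbol_sq(kernel.shape, kernel.voxel_size)
    denom = d**2 + alpha * p
    num = d * np.fft.fftn(phi.data)
    with np.errstate(divide="ignore", invalid="ignore"):
        spec = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), 0.0)
    chi = np.fft.ifftn(spec).real
    return phi.with_data(chi, units_label="ppm")


def _fidelity_weight_sq(params: ADMMParams):
    m = params.fidelity_weight_M
    return None if m is None else np.asarray(m, dtype=float) ** 2


def chi_subproblem(
    v: np.ndarray,
    u: np.ndarray,
    phi: np.ndarray,
    kernel: DipoleKernel,
    params: ADMMParams,
    chi_warm: np.ndarray | None = None,
) -> np.ndarray:
    """Data-consistency update: minimise
    beta/2 ||chi - (v - u)||^2 + mu/2 ||M (A chi - phi)||^2.

    Identity M: exact Fourier solution
    chi = F^H[(beta F(v - u) + mu D F(phi)) / (beta + mu D^2)].
    Otherwise: warm-started conjugate gradients on the normal equations
    (beta I + mu A^H M^2 A) chi = beta (v - u) + mu A^H M^2 phi.
    """
    beta, mu = params.beta, params.mu
    d = kernel.values
    m2 = _fidelity_weight_sq(params)
    if m2 is None:
        spec = (beta * np.fft.fftn(v - u) + mu * d * np.fft.fftn(phi)) / (
            beta + mu * d**2
        )
        return np.fft.ifftn(spec).real

    shape = v.shape
    size = v.size

    def apply_a(x):
        return np.fft.ifftn(d * np.fft.fftn(x)).real

    def matvec(x):
        x = x.reshape(shape)
        out = beta * x + mu * apply_a(m2 * apply_a(x))
        return out.ravel()

    op = LinearOperator((size, size), matvec=matvec, dtype=float)
    rhs = (beta * (v - u) + mu * apply_a(m2 * phi)).ravel()
    x0 = None if chi_warm is None else chi_warm.ravel()
    sol, info = cg(op, rhs, x0=x0, rtol=params.cg_tol, maxiter=params.cg_iters)
    if info > 0:
        res = np.linalg.norm(matvec(sol) - rhs) / max(np.linalg.norm(rhs), 1e-30)
        logger.warning(
            "chi-subproblem CG not converged in %d iterations (rel residual %.3g); "
            "returning best iterate",
            params.cg_iters,
            res,
        )
    return sol.reshape(shape)


def add_noise_back(
    phi_original: VolumeGrid,
    chi_current: VolumeGrid,
    kernel: DipoleKernel,
    lam: float,
) -> VolumeGrid:
    """Remix a fraction of the data residual into the observed field:

    phi_used = phi + lambda * (phi - A chi_current);  lambda = 0 disables.
    """
    if not (0.0 <= lam <= 1.0):
        raise ValueError("lambda must lie in [0, 1]")
    if lam == 0.0:
        return phi_original
    pred = forward_field(chi_current, kernel)
    return phi_original.with_data(
        phi_original.data + lam * (phi_original.data - pred.data)
    )


def _data_residual(chi, phi, kernel, m2):
    r = np.fft.ifftn(kernel.values * np.fft.fftn(chi)).real - phi
    if m2 is not None:
        r = np.sqrt(m2) * r
    return float(np.linalg.norm(r))


def _check_finite(arr, name, iteration, history):
    if not np.all(np.isfinite(arr)):
        raise RuntimeError(
            f"non-finite values in {name} at iteration {iteration}; "
            f"residual history: {history[-3:]}"
        )


def pnp_admm(
    phi: VolumeGrid,
    kernel: DipoleKernel,
    params: ADMMParams,
    initial_chi: VolumeGrid | None = None,
) -> tuple[VolumeGrid, ADMMState]:
    """Plug-and-play ADMM dipole inversion.

    Alternates the chi data-consistency update, v = D_sigma(chi + u) with
    the denoiser named in ``params.denoiser``, and the dual ascent
    u <- u + (chi - v).  Stops at ``max_iters`` or when the relative change
    of chi falls below ``rel_tol``.  Deterministic given its inputs.
    """
    chi = np.zeros(phi.shape) if initial_chi is None else initial_chi.data.astype(float).copy()
    v = chi.copy()
    u = np.zeros_like(chi)
    m2 = _fidelity_weight_sq(params)
    spec = params.denoiser
    sigma = spec.sigma if spec.sigma is not None else float(np.sqrt(params.alpha / params.beta))

    history: list[tuple[float, float]] = []
    it = 0
    for it in range(1, params.max_iters + 1):
        phi_used = phi
        if params.noise_back_lambda > 0:
            phi_used = add_noise_back(
                phi, phi.with_data(chi), kernel, params.noise_back_lambda
            )
        chi_prev = chi
        chi = chi_subproblem(v, u, phi_used.data, kernel, params, chi_warm=chi_prev)
        _check_finite(chi, "chi", it, history)
        noisy_v = phi.with_data(chi + u)
        v = denoise(noisy_v, spec.with_sigma(sigma) if spec.name != "identity" else spec).data
        _check_finite(v, "v", it, history)
        u = u + (chi - v)
        history.append(
            (float(np.linalg.norm(chi - v)), _data_residual(chi, phi.data, kernel, m2))
        )
        sigma *= params.sigma_decay
        rel = np.linalg.norm(chi - chi_prev) / max(np.linalg.norm(chi_prev), 1e-30)
        if rel < params.rel_tol:
            break

    chi_out = phi.with_data(chi * phi.mask if phi.mask is not None else chi, units_label="ppm")
    state = ADMMState(chi=chi, v=v, u=u, iteration=len(history), residual_history=history)
    return chi_out, state


def soft_shrink(g: np.ndarray, t: float, axis: int = 0) -> np.ndarray:
    """Isotropic vector soft-thresholding: max(|g| - t, 0) * g / |g|.

    ``g`` stacks vector components along ``axis``; the magnitude is taken
    across that axis.
    """
    mag = np.sqrt(np.sum(g**2, axis=axis, keepdims=True))
    scale = np.maximum(mag - t, 0.0) / np.where(mag > 0, mag, 1.0)
    return g * scale


def tv_admm(
    phi: VolumeGrid, kernel: DipoleKernel, params: ADMMParams
) -> tuple[VolumeGrid, ADMMState]:
    """Total-variation-regularised inversion (QSM-TV) by ADMM.

    Splits on the gradient field g = grad(chi): the g-update is isotropic
    soft-thresholding of the (optionally W-weighted) gradient at alpha/beta,
    the chi-update is FFT-diagonal for identity M (conjugate gradients for a
    mask/weight M), and the dual ascent mirrors `pnp_admm`'s stopping rule.
    """
    if params.alpha <= 0:
        raise ValueError("alpha must be > 0 for TV")
    vs = kernel.voxel_size
    shape = phi.shape
    d = kernel.values
    e2 = _gradient_symbol_sq(shape, vs)
    m2 = _fidelity_weight_sq(params)
    w = params.tv_weight_W
    mu, alpha, beta = params.mu, params.alpha, params.beta

    # Fourier symbols of the forward-difference operators, for the diagonal path
    e_conj = []
    for ax, (n, dx) in enumerate(zip(shape, vs)):
        f = np.fft.fftfreq(n)
        sym = (np.exp(2j * np.pi * f) - 1.0) / dx
        sh = [1, 1, 1]
        sh[ax] = n
        e_conj.append(np.conj(sym.reshape(sh)))

    chi = np.zeros(shape)
    g = [np.zeros(shape) for _ in range(3)]
    u = [np.zeros(shape) for _ in range(3)]
    history: list[tuple[float, float]] = []
    phi_hat = np.fft.fftn(phi.data)

    for it in range(1, params.max_iters + 1):
        chi_prev = chi
        if m2 is None:
            num = mu * d * phi_hat
            for ax in range(3):
                num = num + beta * e_conj[ax] * np.fft.fftn(g[ax] - u[ax])
            denom = mu * d**2 + beta * e2
            with np.errstate(divide="ignore", invalid="ignore"):
                spec = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), 0.0)
            chi = np.fft.ifftn(spec).real
        else:
            size = chi.size

            def apply_a(x):
                return np.fft.ifftn(d * np.fft.fftn(x)).real

            def matvec(x):
                x = x.reshape(shape)
                out = mu * apply_a(m2 * apply_a(x)) - beta * _div(_grad(x, vs), vs)
                return out.ravel()

            rhs = mu * apply_a(m2 * phi.data) - beta * _div(
                [gi - ui for gi, ui in zip(g, u)], vs
            )
            op = LinearOperator((size, size), matvec=matvec, dtype=float)
            sol, info = cg(
                op, rhs.ravel(), x0=chi.ravel(), rtol=params.cg_tol,
                maxiter=params.cg_iters,
            )
            if info > 0:
                logger.warning("TV chi-update CG not converged (iteration %d)", it)
            chi = sol.reshape(shape)
        _check_finite(chi, "chi", it, history)

        gc = _grad(chi, vs)
        z = np.stack([gi + ui for gi, ui in zip(gc, u)])
        if w is not None:
            z_shrunk = np.where(w > 0, soft_shrink(z * w, alpha / beta) / np.where(w > 0, w, 1.0), z)
        else:
            z_shrunk = soft_shrink(z, alpha / beta)
        g = [z_shrunk[ax] for ax in range(3)]
        u = [ui + (gci - gi) for ui, gci, gi in zip(u, gc, g)]

        primal = float(np.sqrt(sum(np.linalg.norm(gci - gi) ** 2 for gci, gi in zip(gc, g))))
        history.append((primal, _data_residual(chi, phi.data, kernel, m2)))
        rel = np.linalg.norm(chi - chi_prev) / max(np.linalg.norm(chi_prev), 1e-30)
        if rel < params.rel_tol:
            break

    chi_out = phi.with_data(chi * phi.mask if phi.mask is not None else chi, units_label="ppm")
    state = ADMMState(
        chi=chi, v=np.stack(g).sum(axis=0), u=np.stack(u).sum(axis=0),
        iteration=len(history), residual_history=history,
    )
    return chi_out, state
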