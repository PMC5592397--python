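"""Constrained reconstruction of undersampled dynamic MRI via FISTA.

The measurement model is ``B = A X + eps`` with ``A = M F``: a centered
orthonormal 2-D spatial Fourier transform per dynamic followed by a binary
Cartesian sampling mask. Reconstruction solves

    min_X  0.5 ||A X - B||_F^2 + alpha * S(X)

by the accelerated proximal-gradient method (FISTA) where ``S`` is one of
five temporal regularizers:

=====  =======================================================
FT     l1 norm of the 1-D temporal Fourier transform
WT     l1 norm of the 1-D temporal Haar wavelet transform
TV     l1 norm of the temporal gradient (total variation)
TGV    second-order temporal total generalized variation
NN     nuclear norm of the Casorati matrix (mn x d)
ZF     no regularization: the zero-filled baseline
=====  =======================================================

Because the spatial transform is unitary and the mask is a selection, the
data-fidelity gradient has Lipschitz constant 1, so no step-size estimation
is needed. Measured data are rescaled so the zero-filled image has unit
maximum magnitude before iterating (the stock regularization weights assume
this scale) and the output is scaled back.

For TV and TGV the fidelity carries a weight ``lam`` (the objective is
written ``1/(2 lam) ||AX-B||^2 + S_alpha``, equivalently
``0.5 ||AX-B||^2 + lam * S_alpha``), and the prox has no closed form: it is
solved inexactly by a small number of primal-dual iterations per outer step,
or the whole problem can be solved by a standalone primal-dual scheme
(``method="pd"``).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

from . import operators as ops
from .operators import fft2c, ifft2c
from .sampling import MaskSet

__all__ = [
    "ReconConfig",
    "ReconResult",
    "ReconDivergence",
    "TABLE_DEFAULTS",
    "default_config",
    "rescale_to_unit",
    "zero_filled",
    "data_fidelity_grad",
    "fista",
    "reconstruct",
]

REGULARIZERS = ("FT", "WT", "TV", "TGV", "NN", "ZF")


class ReconDivergence(RuntimeError):
    """Raised when the FISTA objective grows beyond 10x its initial value."""


@dataclass
class ReconConfig:
    """Regularizer selection plus solver parameters.

    ``alpha`` weighs the sparsity term; ``n_iter`` caps the outer FISTA
    iterations; ``sigma``/``tau_step`` are the dual/primal steps of the
    TV/TGV inner primal-dual solver and ``lam`` the fidelity weight of those
    two models; ``tol`` is the relative-image-change stopping threshold;
    ``inner_iter`` the primal-dual iterations per prox call;
    ``tgv_ratio`` sets ``alpha0 = tgv_ratio * alpha1`` for TGV.
    """

    regularizer: str
    alpha: float = 0.0
    n_iter: int = 100
    sigma: float = 0.2
    tau_step: float = 0.2
    lam: float = 1.0
    tol: float = 1e-3
    inner_iter: int = 20
    tgv_ratio: float = 2.0
    method: str = "fista"   # "fista" or "pd" (TV/TGV only)

    def __post_init__(self) -> None:
        self.regularizer = self.regularizer.upper()
        if self.regularizer not in REGULARIZERS:
            raise ValueError(f"unknown regularizer {self.regularizer!r}")
        if self.alpha < 0 or self.n_iter < 1 or self.tol <= 0:
            raise ValueError("require alpha >= 0, n_iter >= 1, tol > 0")
        if self.method not in ("fista", "pd"):
            raise ValueError("method must be 'fista' or 'pd'")


#: Stock solver parameters per regularizer (alpha, iterations, and for the
#: TV/TGV models the primal-dual steps sigma = tau = 0.2 and fidelity weight
#: lam = 0.5), valid for data rescaled to unit maximum magnitude.
TABLE_DEFAULTS: dict[str, ReconConfig] = {
    "FT": ReconConfig("FT", alpha=0.059, n_iter=35),
    "WT": ReconConfig("WT", alpha=0.008, n_iter=60),
    "TV": ReconConfig("TV", alpha=0.5, n_iter=100, sigma=0.2, tau_step=0.2, lam=0.5),
    # TGV's joint (z, v) prox subproblem converges more slowly than TV's,
    # so it gets a larger inner primal-dual budget per outer step.
    "TGV": ReconConfig("TGV", alpha=0.5, n_iter=100, sigma=0.2, tau_step=0.2,
                       lam=0.5, inner_iter=40),
    "NN": ReconConfig("NN", alpha=0.3, n_iter=40),
    "ZF": ReconConfig("ZF", alpha=0.0, n_iter=1),
}


def default_config(regularizer: str, **overrides) -> ReconConfig:
    """A fresh copy of the stock configuration for one regularizer."""
    cfg = TABLE_DEFAULTS[regularizer.upper()]
    return replace(copy.deepcopy(cfg), **overrides)


@dataclass
class ReconResult:
    """Reconstruction output with convergence traces."""

    image: np.ndarray
    objective_trace: list[float] = field(default_factory=list)
    rel_change_trace: list[float] = field(default_factory=list)
    iterations_run: int = 0


# ---------------------------------------------------------------------------
# Building blocks
# ---------------------------------------------------------------------------

def _as_mask(maskset) -> np.ndarray:
    mask = maskset.mask if isinstance(maskset, MaskSet) else np.asarray(maskset)
    return mask.astype(float)


def rescale_to_unit(b: np.ndarray, maskset) -> tuple[np.ndarray, float]:
    """Scale data so the zero-filled image has unit maximum magnitude.

    Returns ``(B / s, s)``; multiply the reconstruction by ``s`` to undo.
    """
    mask = _as_mask(maskset)
    zf = ifft2c(np.asarray(b) * mask)
    s = float(np.abs(zf).max())
    if s == 0.0:
        raise ValueError("data are identically zero")
    return np.asarray(b) / s, s


def zero_filled(b: np.ndarray, maskset) -> np.ndarray:
    """Inverse spatial transform with unmeasured k-space entries zeroed."""
    return ifft2c(np.asarray(b) * _as_mask(maskset))


def data_fidelity_grad(x: np.ndarray, b: np.ndarray, maskset) -> np.ndarray:
    """Gradient ``A^H (A X - B)`` of the data-fidelity term.

    With a unitary spatial transform and selection mask the Lipschitz
    constant of this gradient is 1.
    """
    mask = _as_mask(maskset)
    return ifft2c(mask * fft2c(x) - mask * np.asarray(b))


# ---------------------------------------------------------------------------
# FISTA
# ---------------------------------------------------------------------------

def fista(grad_f: Callable[[np.ndarray], np.ndarray], L_f: float,
          prox_g: Callable[[np.ndarray, float], np.ndarray], x0: np.ndarray,
          n_iter: int = 100, tol: float = 1e-3,
          obj_fn: Callable[[np.ndarray], float] | None = None) -> ReconResult:
    """Accelerated proximal-gradient iteration (momentum sequence t_k).

    ``prox_g(x, step)`` must return the proximal map of ``step * g`` at
    ``x``. Stops when the relative image change drops below ``tol`` or at
    ``n_iter``; raises :class:`ReconDivergence` if the tracked objective
    grows beyond 10x its initial value.
    """
    if L_f <= 0:
        raise ValueError("L_f must be positive")
    x_old = np.asarray(x0).copy()
    y = x_old.copy()
    t = 1.0
    step = 1.0 / L_f
    result = ReconResult(image=x_old)
    obj0 = obj_fn(x_old) if obj_fn is not None else None
    for k in range(n_iter):
        x_new = prox_g(y - step * grad_f(y), step)
        t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t))
        y = x_new + ((t - 1.0) / t_new) * (x_new - x_old)
        denom = max(float(np.linalg.norm(x_old)), 1e-30)
        rel = float(np.linalg.norm(x_new - x_old)) / denom
        result.rel_change_trace.append(rel)
        if obj_fn is not None:
            val = float(obj_fn(x_new))
            result.objective_trace.append(val)
            if obj0 is not None and np.isfinite(obj0) and val > 10.0 * max(obj0, 1e-30):
                raise ReconDivergence(
                    f"objective grew from {obj0:.3e} to {val:.3e} at iteration {k}")
        x_old = x_new
        t = t_new
        result.iterations_run = k + 1
        if rel < tol:
            break
    result.image = x_old
    return result


# ---------------------------------------------------------------------------
# Standalone primal-dual reconstruction (TV/TGV alternative mode)
# ---------------------------------------------------------------------------

def _pd_recon(b, mask, cfg: ReconConfig) -> np.ndarray:
    """Chambolle-Pock on 0.5||AX-B||^2 + w ||D X||_1 (+ TGV coupling)."""
    w = cfg.lam * cfg.alpha
    tgv = cfg.regularizer == "TGV"
    d = b.shape[-1]
    # conservative step sizes: ||A|| = 1, ||D|| <= 2
    l2 = 1.0 + (ops.TGV_NORM_SQ if tgv else ops.GRAD_NORM_SQ)
    sigma = tau = 0.95 / np.sqrt(l2)
    x = zero_filled(b, mask)
    xbar = x.copy()
    r = np.zeros_like(b)                      # dual of A
    q = np.zeros_like(x)                      # dual of D (TV)
    if tgv:
        a1, a0 = w, cfg.tgv_ratio * w
        vshape = x.shape[:-1] + (d - 1,)
        v = np.zeros(vshape, dtype=x.dtype)
        vbar = v.copy()
        p = np.zeros(vshape, dtype=x.dtype)
        q2 = np.zeros(x.shape[:-1] + (max(d - 2, 0),), dtype=x.dtype)
    for _ in range(cfg.n_iter):
        r = (r + sigma * (mask * fft2c(xbar) - mask * b)) / (1.0 + sigma)
        if tgv:
            p = ops._clamp_magnitude(p + sigma * (ops._diff_last(xbar) - vbar), a1)
            if d > 2:
                q2 = ops._clamp_magnitude(q2 + sigma * ops._diff_last(vbar), a0)
            x_old = x
            x = x - tau * (ifft2c(mask * r) + ops._diff_last_adjoint(p, d))
            v_old = v
            dtq = ops._diff_last_adjoint(q2, d - 1) if d > 2 else 0.0
            v = v + tau * (p - dtq)
            vbar = 2.0 * v - v_old
        else:
            q = ops._clamp_magnitude(q + sigma * ops.temporal_diff(xbar), w)
            x_old = x
            x = x - tau * (ifft2c(mask * r) + ops.temporal_diff_adjoint(q))
        xbar = 2.0 * x - x_old
    return x


# ---------------------------------------------------------------------------
# Dispatch
# ---------------------------------------------------------------------------

def _prox_and_objective(cfg: ReconConfig, shape: tuple[int, ...]):
    """Prox callable ``(x, step) -> x`` and sparsity-value callable for S."""
    d = shape[-1]
    reg = cfg.regularizer
    if reg == "FT":
        op = ops.temporal_dft_op(d)
        return (lambda x, s: ops.prox_l1_unitary(op, x, cfg.alpha * s),
                lambda x: cfg.alpha * float(np.abs(op.forward(x)).sum()))
    if reg == "WT":
        op = ops.temporal_haar_op(d)
        return (lambda x, s: ops.prox_l1_unitary(op, x, cfg.alpha * s),
                lambda x: cfg.alpha * float(np.abs(op.forward(x)).sum()))
    if reg == "NN":
        def prox(x, s):
            cas = x.reshape(-1, d)
            return ops.prox_nuclear(cas, cfg.alpha * s).reshape(x.shape)

        def value(x):
            return cfg.alpha * float(np.linalg.svd(x.reshape(-1, d),
                                                   compute_uv=False).sum())
        return prox, value
    if reg == "TV":
        w = cfg.lam * cfg.alpha
        state: dict = {}  # warm-started duals keep the inexact prox accurate
        return (lambda x, s: ops.tv_denoise(x, w * s, n_iter=cfg.inner_iter,
                                            sigma=cfg.sigma, tau_step=cfg.tau_step,
                                            state=state),
                lambda x: w * float(np.abs(ops.temporal_diff(x)).sum()))
    if reg == "TGV":
        w = cfg.lam * cfg.alpha
        state = {}
        def tgv_value(x):
            # evaluate the inner minimum over v with the current estimate
            v = state.get("v")
            dz = ops._diff_last(x)
            if v is None:
                return w * float(np.abs(dz).sum())
            d2v = ops._diff_last(v) if v.shape[-1] > 1 else np.zeros(1)
            return w * float(np.abs(dz - v).sum()) + cfg.tgv_ratio * w * float(np.abs(d2v).sum())
        return (lambda x, s: ops.tgv_denoise(x, alpha1=w * s,
                                             alpha0=cfg.tgv_ratio * w * s,
                                             n_iter=cfg.inner_iter,
                                             sigma=cfg.sigma, tau_step=cfg.tau_step,
                                             state=state),
                tgv_value)
    raise ValueError(f"no prox for regularizer {reg!r}")


def reconstruct(b: np.ndarray, maskset, config: ReconConfig) -> ReconResult:
    """Reconstruct undersampled k-space ``b`` under one regularizer.

    ``b`` is centered k-space (rows, cols, dynamics); entries outside the
    mask are ignored. The output is returned in the input units.
    """
    mask = _as_mask(maskset)
    b = np.asarray(b, dtype=complex)
    if mask.shape != b.shape:
        raise ValueError("mask and data shapes disagree")
    if config.regularizer == "ZF":
        return ReconResult(image=zero_filled(b, mask), iterations_run=0)
    b_scaled, scale = rescale_to_unit(b, mask)
    x0 = zero_filled(b_scaled, mask)
    if config.method == "pd" and config.regularizer in ("TV", "TGV"):
        x = _pd_recon(b_scaled, mask, config)
        return ReconResult(image=x * scale, iterations_run=config.n_iter)
    prox_g, s_value = _prox_and_objective(config, b.shape)
    mb = mask * b_scaled

    def grad(x):
        return ifft2c(mask * fft2c(x) - mb)

    def obj(x):
        resid = mask * fft2c(x) - mb
        return 0.5 * float(np.vdot(resid, resid).real) + s_value(x)

    result = fista(grad, 1.0, prox_g, x0, n_iter=config.n_iter,
                   tol=config.tol, obj_fn=obj)
    result.image = result.image * scale
    return result
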