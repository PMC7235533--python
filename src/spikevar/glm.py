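"""The nested Poisson GLM hierarchy and its GP-MAP block fits.

Spike counts y_ti (trial i, bin t) are modelled as Poisson with per-bin
mean mu_ti = exp(z_ti), where the activation grows through four nested
levels:

    BS       z = b0                      constant mean rate
    NS       z = b0 + phi_i              + slow per-trial drift
    NS-LNP   z = b0 + phi_i + x_t.k      + linear stimulus filter
    NS-PSTH  z = b0 + phi_i + x_t.k + rho_t   + per-bin modulation

b0 absorbs the bin width, so exp(z) is a mean count per bin; firing rates
are exp(z)/delta_t for display only. Each added block (phi, k, rho) is
MAP-fitted under a zero-mean Gaussian-process prior while every earlier
block stays fixed, via damped Newton iterations on the concave penalized
log-likelihood. A prior scale of 0 pins the block to zero (the collapse
point of the hierarchy).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import cho_factor, cho_solve, solveh_banded
from scipy.special import gammaln, xlogy

from .data import SpikeRaster
from .design import StimulusDesign
from .kernels import KernelSpec, ar1_precision_diagonals, gp_conditional_mean, kernel_matrix

__all__ = [
    "LEVELS",
    "ModelParams",
    "ConvergenceError",
    "activation",
    "activation_matrix",
    "poisson_loglik",
    "fit_baseline",
    "fit_map_block",
    "saturated_loglik",
    "predict_phi",
]

logger = logging.getLogger(__name__)

LEVELS = ("BS", "NS", "NS-LNP", "NS-PSTH")
_BLOCK_LEVEL = {"phi": "NS", "k": "NS-LNP", "rho": "NS-PSTH"}

#: activation clip before exponentiation; far outside plausible rates
Z_CLIP = 30.0


class ConvergenceError(RuntimeError):
    """Newton solver failed; carries iterate diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


@dataclass
class ModelParams:
    """Parameters of one hierarchy level.

    Blocks above the level are identically zero; ``free`` records which
    blocks were actually optimized (vs fixed or pinned).
    """

    b0: float
    phi: np.ndarray
    k: np.ndarray
    rho: np.ndarray
    level: str = "BS"
    free: tuple[str, ...] = ()
    hyper: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise ValueError(f"level must be one of {LEVELS}")
        self.phi = np.asarray(self.phi, dtype=float)
        self.k = np.asarray(self.k, dtype=float)
        self.rho = np.asarray(self.rho, dtype=float)

    @classmethod
    def zeros(cls, K: int, m: int, T: int, b0: float = 0.0, level: str = "BS") -> "ModelParams":
        return cls(b0=b0, phi=np.zeros(K), k=np.zeros(m), rho=np.zeros(T), level=level)

    def with_block(self, block: str, value: np.ndarray, hyper: dict | None = None) -> "ModelParams":
        new = replace(self, **{("k" if block == "k" else block): np.asarray(value, dtype=float)})
        new.level = _BLOCK_LEVEL[block]
        new.free = (block,)
        if hyper is not None:
            new.hyper = {**self.hyper, **hyper}
        return new


def _drive(design: StimulusDesign | None, k: np.ndarray, K: int, T: int) -> np.ndarray:
    if design is None or not k.any():
        return np.zeros((1, T))
    s = design.drive(k)
    return s[None, :] if s.ndim == 1 else s  # (1,T) shared or (K,T)


def activation_matrix(params: ModelParams, design: StimulusDesign | None, K: int, T: int) -> np.ndarray:
    """Full K x T activation z_ti; absent blocks contribute zero."""
    return params.b0 + params.phi[:, None] + _drive(design, params.k, K, T) + params.rho[None, :]


def activation(params: ModelParams, design: StimulusDesign | None, i: int, t: int) -> float:
    """Activation of a single (trial, bin) cell."""
    K, T = len(params.phi), len(params.rho)
    if not (0 <= i < K and 0 <= t < T):
        raise IndexError("trial or bin index out of range")
    z = params.b0 + params.phi[i] + params.rho[t]
    if design is not None and params.k.any():
        x = design.X[t] if design.shared else design.X[i, t]
        z += float(x @ params.k)
    return float(z)


def _masked(Y: np.ndarray, z: np.ndarray, bin_mask: np.ndarray | None):
    if bin_mask is None:
        return Y, z
    return Y[:, bin_mask], z[:, bin_mask]


def poisson_loglik(
    params: ModelParams,
    raster: SpikeRaster,
    design: StimulusDesign | None = None,
    bin_mask: np.ndarray | None = None,
    z_clip: float = Z_CLIP,
) -> float:
    """Poisson log-likelihood sum_ti [y z - exp(z) - log(y!)].

    The log(y!) term is kept so that differences against the saturated
    model are coherent. Activations beyond ``z_clip`` in magnitude are
    clipped (with a warning) to guard the exponential.
    """
    Y = raster.counts
    z = activation_matrix(params, design, *Y.shape)
    z = np.broadcast_to(z, Y.shape)
    Y, z = _masked(Y, z, bin_mask)
    if np.abs(z).max(initial=0.0) > z_clip:
        warnings.warn(f"activation clipped at +/-{z_clip}", RuntimeWarning, stacklevel=2)
        z = np.clip(z, -z_clip, z_clip)
    return float((Y * z - np.exp(z) - gammaln(Y + 1.0)).sum())


def saturated_loglik(raster: SpikeRaster, bin_mask: np.ndarray | None = None) -> float:
    """Log-likelihood upper bound: each bin's mean set to its own count.

    sum_ti [y log y - y - log(y!)], with 0 log 0 = 0.
    """
    Y = raster.counts
    if bin_mask is not None:
        Y = Y[:, bin_mask]
    Yf = Y.astype(float)
    return float((xlogy(Yf, Yf) - Yf - gammaln(Yf + 1.0)).sum())


def fit_baseline(
    raster: SpikeRaster,
    design: StimulusDesign | None = None,
    bin_mask: np.ndarray | None = None,
    floor: float | None = None,
) -> ModelParams:
    """Fit the constant-rate baseline: exp(b0) = mean count per bin.

    A raster with zero spikes gets b0 = log(floor) (default floor
    1/(10 T K)) with a warning, keeping later likelihoods finite.
    """
    if raster.counts.size == 0:
        raise ValueError("raster is empty")
    Y = raster.counts if bin_mask is None else raster.counts[:, bin_mask]
    K, T = raster.counts.shape
    mean_count = Y.mean()
    if mean_count <= 0:
        if floor is None:
            floor = 1.0 / (10.0 * Y.size)
        warnings.warn(
            f"no spikes: baseline mean floored at {floor:.3g} counts/bin", RuntimeWarning,
            stacklevel=2,
        )
        mean_count = floor
    m = design.m if design is not None else 1
    p = ModelParams.zeros(K, m, T, b0=float(np.log(mean_count)), level="BS")
    p.free = ("b0",)
    return p


def predict_phi(
    phi_train: np.ndarray,
    train_ids: np.ndarray,
    test_ids: np.ndarray,
    prior: KernelSpec,
) -> np.ndarray:
    """Extend fitted per-trial offsets to unseen trials by GP interpolation.

    This is the profile of the joint MAP when held-out trials contribute no
    likelihood terms: their offsets sit at the prior conditional mean given
    the fitted trials.
    """
    return gp_conditional_mean(prior, train_ids, phi_train, test_ids)


# ---------------------------------------------------------------------------
# MAP block fitting


def _block_geometry(block, Y, design, bin_mask):
    """Per-block gradient / Hessian-diag contractions for the Newton solver.

    Returns (n, grad_fn, hess_fn, contrib_fn, mask): ``grad_fn`` maps the
    residual matrix (Y - mu) to the likelihood gradient over the block,
    ``hess_fn`` maps mu to the (negated) likelihood Hessian (dense matrix
    for phi/k, diagonal vector for rho), and ``contrib_fn`` maps the block
    to its additive term in the activation.
    """
    K, T = Y.shape
    mask = np.ones(T, dtype=bool) if bin_mask is None else np.asarray(bin_mask, dtype=bool)

    if block == "phi":
        def grad(resid):  # resid has masked columns zeroed
            return resid.sum(axis=1)

        def hess(mu):
            return np.diag(mu.sum(axis=1))

        def contrib(theta):
            return theta[:, None]

        n = K
    elif block == "k":
        if design is None:
            raise ValueError("fitting the filter block requires a stimulus design")
        X = design.X
        shared = design.shared

        def grad(resid):
            if shared:
                return X.T @ resid.sum(axis=0)
            return np.einsum("it,itm->m", resid, X)

        def hess(mu):
            if shared:
                w = mu.sum(axis=0)
                return X.T @ (w[:, None] * X)
            return np.einsum("it,itm,itn->mn", mu, X, X)

        def contrib(theta):
            s = X @ theta
            return s[None, :] if shared else s

        n = design.m
    elif block == "rho":
        def grad(resid):
            return resid.sum(axis=0)

        def hess(mu):  # diagonal only
            return mu.sum(axis=0)

        def contrib(theta):
            return theta[None, :]

        n = T
    else:
        raise ValueError("block must be one of 'phi', 'k', 'rho'")
    return n, grad, hess, contrib, mask


def fit_map_block(
    raster: SpikeRaster,
    design: StimulusDesign | None,
    params_fixed: ModelParams,
    block: str,
    prior: KernelSpec,
    bin_mask: np.ndarray | None = None,
    trial_index: np.ndarray | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
    z_clip: float = Z_CLIP,
) -> ModelParams:
    """MAP-fit one parameter block under its GP prior, others fixed.

    Maximizes ``loglik(theta) - 0.5 theta' C^{-1} theta`` over the named
    block by Newton iterations with backtracking (the objective is concave,
    so steps are damped until they improve it), to relative objective
    change ``tol``. A prior scale of 0 returns the block as exact zeros
    without optimization. The AR(1) prior on rho is applied through its
    tridiagonal precision so the T-dimensional solve stays banded.
    """
    Y = raster.counts.astype(float)
    K, T = Y.shape
    hyper = {block: prior}
    if prior.scale == 0:
        n = {"phi": K, "k": design.m if design is not None else len(params_fixed.k), "rho": T}[block]
        return params_fixed.with_block(block, np.zeros(n), hyper)

    n, grad_fn, hess_fn, contrib_fn, mask = _block_geometry(block, Y, design, bin_mask)

    # prior precision: banded for the AR(1) prior on rho, dense otherwise
    banded = block == "rho" and prior.family == "ar1"
    if banded:
        q_main, q_off = ar1_precision_diagonals(prior, n)

        def prior_quad(theta):
            return float(theta @ (q_main * theta) + 2.0 * theta[:-1] @ (q_off * theta[1:]))

        def prior_grad(theta):
            g = q_main * theta
            g[:-1] += q_off * theta[1:]
            g[1:] += q_off * theta[:-1]
            return g
    else:
        index = trial_index if (block == "phi" and trial_index is not None) else None
        C = kernel_matrix(prior, n, index)
        try:
            cC = cho_factor(C, lower=True)
        except np.linalg.LinAlgError as exc:
            raise ValueError("prior covariance is not positive definite") from exc
        P_dense = cho_solve(cC, np.eye(n))

        def prior_quad(theta):
            return float(theta @ (P_dense @ theta))

        def prior_grad(theta):
            return P_dense @ theta

    # activation with the block removed
    base = replace(params_fixed, **{block: np.zeros(n)})
    z_base = activation_matrix(base, design, K, T)
    z_base = np.broadcast_to(z_base, Y.shape).copy()

    Ym = Y.copy()
    Ym[:, ~mask] = 0.0  # masked bins contribute nothing

    def objective(theta):
        z = np.clip(z_base + contrib_fn(theta), -z_clip, z_clip)
        mu = np.exp(z)
        mu[:, ~mask] = 0.0
        ll = float((Ym * z).sum() - mu.sum())
        return ll - 0.5 * prior_quad(theta), mu

    theta = np.zeros(n)
    f, mu = objective(theta)
    converged = False
    for it in range(max_iter):
        resid = Ym - mu
        g = grad_fn(resid) - prior_grad(theta)
        if banded:
            ab = np.zeros((2, n))
            ab[0, 1:] = q_off
            ab[1] = q_main + hess_fn(mu)
            step_dir = solveh_banded(ab, g)
        else:
            H = hess_fn(mu) + P_dense
            step_dir = cho_solve(cho_factor(H, lower=True), g)

        # backtracking: concave objective, so a short enough step improves it
        alpha = 1.0
        f_new, mu_new = f, mu
        for _ in range(60):
            f_new, mu_new = objective(theta + alpha * step_dir)
            if f_new >= f:
                break
            alpha *= 0.5
        else:
            if np.max(np.abs(g)) < 1e-6:
                converged = True
                break
            raise ConvergenceError(
                "backtracking failed to improve the MAP objective",
                {"iter": it, "objective": f, "grad_max": float(np.max(np.abs(g)))},
            )
        theta = theta + alpha * step_dir
        improvement = f_new - f
        f, mu = f_new, mu_new
        if improvement <= tol * (1.0 + abs(f)):
            converged = True
            break
    if not converged:
        raise ConvergenceError(
            f"MAP fit of block {block!r} did not converge in {max_iter} iterations",
            {"objective": f, "grad_max": float(np.max(np.abs(g)))},
        )
    return params_fixed.with_block(block, theta, hyper)
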