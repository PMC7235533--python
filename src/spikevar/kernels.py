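"""Gaussian-process priors used to regularize the GLM parameter blocks.

Two covariance families are supported:

* ``matern`` — the Matérn kernel with half-integer smoothness ``nu``
  (default 3/2), used for the per-trial drift offsets and the stimulus
  filter taps.
* ``ar1`` — the covariance of a discretized Ornstein-Uhlenbeck process,
  ``C_ij = scale^2 * corr^|i-j|``, used for the per-bin rate modulation.
  Its precision matrix is tridiagonal, which keeps the high-dimensional
  Newton solves banded.

A ``scale`` of exactly 0 is the collapse point: the corresponding
parameter block is pinned to zero instead of being optimized.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["KernelSpec", "kernel_matrix", "ar1_precision_diagonals", "gp_conditional_mean"]


@dataclass(frozen=True)
class KernelSpec:
    """Description of a GP prior over an integer-like index set.

    Parameters
    ----------
    family : {"matern", "ar1"}
    scale : float
        Prior standard deviation sigma >= 0. A scale of 0 pins the block to 0.
    length : float, optional
        Matérn length scale tau > 0, in index units. Required for "matern".
    corr : float, optional
        AR(1) lag-one correlation a in [0, 1). Required for "ar1".
    nu : float
        Matérn smoothness; one of 0.5, 1.5, 2.5. Default 1.5.
    jitter : float
        Small diagonal added to realized covariance matrices for numerical
        positive-definiteness.
    """

    family: str
    scale: float
    length: float | None = None
    corr: float | None = None
    nu: float = 1.5
    jitter: float = 1e-8

    def __post_init__(self) -> None:
        if self.family not in ("matern", "ar1"):
            raise ValueError(f"unknown kernel family {self.family!r}")
        if not np.isfinite(self.scale) or self.scale < 0:
            raise ValueError("scale must be a finite non-negative real")
        if self.family == "matern":
            if self.length is None or not self.length > 0:
                raise ValueError("matern kernel requires length > 0")
            if self.nu not in (0.5, 1.5, 2.5):
                raise ValueError("nu must be one of 0.5, 1.5, 2.5")
        else:
            if self.corr is None or not (0.0 <= self.corr < 1.0):
                raise ValueError("ar1 kernel requires corr in [0, 1)")


def _matern_corr(d: np.ndarray, tau: float, nu: float) -> np.ndarray:
    r = np.abs(d) / tau
    if nu == 0.5:
        return np.exp(-r)
    if nu == 1.5:
        s = np.sqrt(3.0) * r
        return (1.0 + s) * np.exp(-s)
    s = np.sqrt(5.0) * r
    return (1.0 + s + s * s / 3.0) * np.exp(-s)


def kernel_matrix(spec: KernelSpec, n: int, index: np.ndarray | None = None) -> np.ndarray:
    """Realize ``spec`` as an ``n x n`` covariance matrix.

    ``index`` gives the positions of the n points (default ``0..n-1``);
    distances are ``|index_i - index_j|``. The jitter is added to the
    diagonal.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if index is None:
        index = np.arange(n, dtype=float)
    index = np.asarray(index, dtype=float)
    if index.shape != (n,):
        raise ValueError("index must have length n")
    d = np.abs(index[:, None] - index[None, :])
    if spec.family == "matern":
        cov = spec.scale**2 * _matern_corr(d, spec.length, spec.nu)
    else:
        cov = spec.scale**2 * spec.corr**d
    return cov + spec.jitter * np.eye(n)


def ar1_precision_diagonals(spec: KernelSpec, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Tridiagonal precision of an AR(1) covariance on a unit-spaced grid.

    Returns ``(main, off)`` with ``main`` of length n and ``off`` of
    length n-1 such that ``Q = tridiag(off, main, off)`` satisfies
    ``Q @ C = I`` for ``C_ij = scale^2 corr^|i-j|`` (without jitter).
    """
    if spec.family != "ar1":
        raise ValueError("tridiagonal precision only exists for the ar1 family")
    if spec.scale <= 0:
        raise ValueError("precision undefined for scale 0")
    a = spec.corr
    s2 = spec.scale**2
    main = np.full(n, (1.0 + a * a) / (s2 * (1.0 - a * a)))
    if n >= 1:
        main[0] = main[-1] = 1.0 / (s2 * (1.0 - a * a))
    if n == 1:
        main[0] = 1.0 / s2
    off = np.full(max(n - 1, 0), -a / (s2 * (1.0 - a * a)))
    return main, off


def gp_conditional_mean(
    spec: KernelSpec,
    train_index: np.ndarray,
    train_values: np.ndarray,
    test_index: np.ndarray,
) -> np.ndarray:
    """Posterior (conditional) mean of a zero-mean GP at ``test_index``.

    Used to extend MAP estimates of the per-trial drift to held-out
    trials: the joint MAP with likelihood terms only on training trials
    profiles to exactly this extension.
    """
    train_index = np.asarray(train_index, dtype=float)
    test_index = np.asarray(test_index, dtype=float)
    if spec.scale == 0:
        return np.zeros(len(test_index))
    c_tt = kernel_matrix(spec, len(train_index), train_index)
    d = np.abs(test_index[:, None] - train_index[None, :])
    if spec.family == "matern":
        c_xt = spec.scale**2 * _matern_corr(d, spec.length, spec.nu)
    else:
        c_xt = spec.scale**2 * spec.corr**d
    return c_xt @ np.linalg.solve(c_tt, np.asarray(train_values, dtype=float))
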