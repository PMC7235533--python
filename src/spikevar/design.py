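"""Stimulus history design: per-bin vectors x_t = (x_t, x_{t-1}, ..., x_{t-m+1}).

The linear-filter stage of the model hierarchy scores each bin by the dot
product of its m-bin stimulus history with the filter taps (lag 0 = the
bin's own pulse). Frozen-noise trials share one realization, so their
design collapses to a single T x m matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import StimulusSet

__all__ = ["StimulusDesign", "build_design"]


@dataclass
class StimulusDesign:
    """History matrix plus the conventions used to build it.

    ``X`` is (T, m) when all covered trials share one stimulus realization,
    else (K, T, m). ``incomplete`` flags bins t < m-1 whose history was
    zero-padded (or masked out under ``history='drop'``). ``bin_mask`` marks
    the bins that enter likelihoods (all True under padding).
    """

    X: np.ndarray
    m: int
    incomplete: np.ndarray
    bin_mask: np.ndarray
    standardized: bool = True
    center_mV: float = 0.0
    scale_mV: float = 1.0

    @property
    def shared(self) -> bool:
        return self.X.ndim == 2

    @property
    def n_bins(self) -> int:
        return self.X.shape[-2]

    def drive(self, k: np.ndarray) -> np.ndarray:
        """Stimulus drive x_t.k — (T,) if shared, else (K, T)."""
        return self.X @ k


def _history_matrix(x: np.ndarray, m: int) -> np.ndarray:
    T = len(x)
    X = np.zeros((T, m))
    for j in range(m):
        X[j:, j] = x[: T - j]
    return X


def build_design(
    stimulus: StimulusSet,
    m: int = 25,
    n_bins: int | None = None,
    standardize: bool = True,
    history: str = "pad",
    frozen_only: bool = True,
) -> StimulusDesign:
    """Build the stimulus-history design from pulse amplitudes.

    With ``standardize`` (default) amplitudes are z-scored with the moments
    of the covered trials before entering the design, so filter taps and
    their GP prior live on an order-one scale regardless of the mV units.
    ``history`` chooses how bins with incomplete history are handled:
    ``'pad'`` zero-pads and keeps them (flagged); ``'drop'`` removes them
    from the likelihood via ``bin_mask``.
    """
    if m < 1:
        raise ValueError("m must be a positive count")
    if history not in ("pad", "drop"):
        raise ValueError("history must be 'pad' or 'drop'")
    amps = stimulus.amplitudes
    if frozen_only:
        if not stimulus.is_frozen.any():
            raise ValueError("no frozen trials to build a design from")
        amps = amps[stimulus.is_frozen]
    T = n_bins if n_bins is not None else amps.shape[1]
    if T > amps.shape[1]:
        raise ValueError("fewer pulses than requested bins")
    if m > T:
        raise ValueError("filter length m exceeds the number of bins")
    amps = amps[:, :T].astype(float)
    center, scale = 0.0, 1.0
    if standardize:
        center = float(amps.mean())
        scale = float(amps.std())
        if scale == 0:
            scale = 1.0
        amps = (amps - center) / scale

    shared = bool(np.all(amps == amps[0]))
    if shared:
        X = _history_matrix(amps[0], m)
    else:
        X = np.stack([_history_matrix(row, m) for row in amps])
    incomplete = np.zeros(T, dtype=bool)
    incomplete[: m - 1] = True
    bin_mask = np.ones(T, dtype=bool)
    if history == "drop":
        bin_mask[: m - 1] = False
    return StimulusDesign(
        X=X,
        m=m,
        incomplete=incomplete,
        bin_mask=bin_mask,
        standardized=standardize,
        center_mV=center,
        scale_mV=scale,
    )
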