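"""Diagnostic figures: raster, STA, per-trial firing rate."""

from __future__ import annotations

import numpy as np

from .data import SpikeRaster
from .preprocess import STAEstimate

__all__ = ["plot_raster", "plot_sta", "plot_trial_rates"]


def plot_raster(raster: SpikeRaster, ax=None):
    """Spike raster: one row per trial, tick positions at bin centres weighted by count."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for i in range(raster.n_trials):
        t = np.repeat(np.arange(raster.n_bins), raster.counts[i]) * raster.delta_t
        ax.plot(t, np.full_like(t, i, dtype=float), "|", color="k", markersize=3)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("trial")
    return ax


def plot_sta(sta: STAEstimate, delta_t: float = 0.04, ax=None):
    """STA taps against lag (s before the spike), with the shuffle band if present."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    lags = -np.arange(len(sta.taps)) * delta_t
    ax.plot(lags, sta.taps, "o-", color="C0")
    if sta.shuffle_band is not None:
        ax.fill_between(lags, sta.shuffle_band[0], sta.shuffle_band[1], alpha=0.3, color="gray")
    ax.axhline(0, color="k", lw=0.5)
    ax.set_xlabel("lag (s)")
    ax.set_ylabel("STA (mV)" if not sta.centered else "STA (mV, centered)")
    return ax


def plot_trial_rates(raster: SpikeRaster, predicted_hz: np.ndarray | None = None, ax=None):
    """Empirical per-trial mean firing rate, optionally with a model prediction."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    rate = raster.counts.mean(axis=1) / raster.delta_t
    ax.plot(raster.trial_ids, rate, "ko-", label="empirical")
    if predicted_hz is not None:
        ax.plot(raster.trial_ids, predicted_hz.mean(axis=1), "C1o-", label="model")
        ax.legend()
    ax.set_xlabel("trial")
    ax.set_ylabel("rate (Hz)")
    return ax
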