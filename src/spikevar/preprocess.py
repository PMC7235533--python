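"""Spike-time binning and classical spike-triggered averaging.

Spike trains are discretized into pulse-aligned bins of width ``delta_t``
(default 40 ms, one bin per 25 Hz pulse). Spikes inside the first
``dead_time`` seconds after each pulse (default 10 ms) are discarded to
exclude direct electrical activation; the discard is counted, not silent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .data import SpikeRaster, StimulusSet
from .rng import substream

__all__ = ["bin_spikes", "compute_sta", "sta_shuffle_test", "STAEstimate", "ShuffleTestResult"]

logger = logging.getLogger(__name__)


@dataclass
class STAEstimate:
    """Spike-triggered average over m causal taps.

    ``taps[j]`` is the mean stimulus value j bins before (and including)
    the spike's own bin; computed over bins with a full m-bin history.
    """

    taps: np.ndarray
    n_spikes_used: int
    centered: bool
    shuffle_band: np.ndarray | None = None


@dataclass
class ShuffleTestResult:
    sta: STAEstimate
    lower: np.ndarray
    upper: np.ndarray
    significant: bool
    alpha: float
    n_shuffles: int


def bin_spikes(
    spike_times: Sequence[np.ndarray],
    pulse_times: Sequence[np.ndarray],
    delta_t: float = 0.04,
    dead_time: float = 0.01,
    is_frozen: np.ndarray | None = None,
    trial_ids: np.ndarray | None = None,
) -> SpikeRaster:
    """Bin per-trial spike times into pulse-aligned counts.

    A spike at time s in trial i lands in bin t iff
    ``pulse_t <= s < pulse_t + delta_t`` and ``s - pulse_t >= dead_time``
    (half-open bins: a boundary spike belongs to the later bin). Spikes in
    the dead window are dropped and counted; spikes before the first pulse
    or past the last bin are dropped as out-of-range and counted.
    """
    if not delta_t > 0:
        raise ValueError("delta_t must be positive")
    if not 0.0 <= dead_time < delta_t:
        raise ValueError("dead_time must lie in [0, delta_t)")
    if len(spike_times) != len(pulse_times):
        raise ValueError("spike_times and pulse_times must cover the same trials")
    n_pulses = {len(p) for p in pulse_times}
    if len(n_pulses) != 1:
        raise ValueError(f"unequal pulse counts across trials: {sorted(n_pulses)}")
    T = n_pulses.pop()
    if T == 0:
        raise ValueError("trials contain no pulses")

    K = len(spike_times)
    counts = np.zeros((K, T), dtype=np.int64)
    n_dead = 0
    n_range = 0
    for i in range(K):
        pulses = np.asarray(pulse_times[i], dtype=float)
        if (np.diff(pulses) <= 0).any():
            raise ValueError(f"pulse times must be strictly increasing (trial {i})")
        s = np.asarray(spike_times[i], dtype=float)
        if s.size == 0:
            continue
        idx = np.searchsorted(pulses, s, side="right") - 1
        before = idx < 0
        offset = s - pulses[np.clip(idx, 0, T - 1)]
        out = before | (offset >= delta_t)
        dead = ~out & (offset < dead_time)
        keep = ~out & ~dead
        n_range += int(out.sum())
        n_dead += int(dead.sum())
        np.add.at(counts[i], idx[keep], 1)
    if n_dead or n_range:
        logger.info("bin_spikes dropped %d dead-time and %d out-of-range spikes", n_dead, n_range)
    return SpikeRaster(
        counts=counts,
        delta_t=delta_t,
        trial_ids=trial_ids,
        is_frozen=is_frozen,
        dead_time=dead_time,
        n_dropped_dead=n_dead,
        n_dropped_range=n_range,
    )


def _sta_from_counts(counts: np.ndarray, amplitudes: np.ndarray, m: int) -> tuple[np.ndarray, int]:
    """STA over bins t >= m-1 (full history). Returns (taps, n_spikes_used)."""
    K, T = counts.shape
    y = counts[:, m - 1 :].astype(float)
    n_sp = y.sum()
    if n_sp == 0:
        raise ValueError("STA undefined: no spikes in bins with full stimulus history")
    taps = np.empty(m)
    for j in range(m):
        x = amplitudes[:, m - 1 - j : T - j]
        taps[j] = float((y * x).sum()) / n_sp
    return taps, int(n_sp)


def compute_sta(
    raster: SpikeRaster,
    stimulus: StimulusSet,
    m: int,
    center: bool = True,
) -> STAEstimate:
    """Spike-triggered average of the pulse amplitudes.

    Tap j averages the pulse j bins before the spike's bin (lag 0 = the
    spike's own bin), restricted to bins with a full m-bin history. With
    ``center`` the stimulus mean is removed first, so a stimulus-blind cell
    gives taps near 0 instead of the -800 mV pulse mean.
    """
    if not 0 < m <= raster.n_bins:
        raise ValueError("m must satisfy 0 < m <= number of bins")
    if stimulus.n_trials != raster.n_trials:
        raise ValueError("stimulus and raster trial counts differ")
    amps = stimulus.amplitudes[:, : raster.n_bins].astype(float)
    if center:
        amps = amps - amps.mean()
    taps, n_used = _sta_from_counts(raster.counts, amps, m)
    return STAEstimate(taps=taps, n_spikes_used=n_used, centered=center)


def sta_shuffle_test(
    raster: SpikeRaster,
    stimulus: StimulusSet,
    m: int,
    n_shuffles: int = 500,
    seed: int = 0,
    alpha: float = 0.01,
    center: bool = True,
) -> ShuffleTestResult:
    """Circular-shift surrogate test for STA significance.

    Each trial's spike-count sequence is circularly shifted by an
    independent random offset, destroying the spike-stimulus alignment
    while preserving counts and autostructure; the per-tap [alpha/2,
    1-alpha/2] quantile envelope of the surrogate STAs is the null band.
    The STA is flagged significant iff any tap exits the band.
    """
    if n_shuffles < 100:
        raise ValueError("n_shuffles must be at least 100")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    sta = compute_sta(raster, stimulus, m, center=center)
    amps = stimulus.amplitudes[:, : raster.n_bins].astype(float)
    if center:
        amps = amps - amps.mean()
    rng = substream(seed, "sta_shuffle")
    K, T = raster.counts.shape
    surrogates = np.empty((n_shuffles, m))
    for s in range(n_shuffles):
        shifted = np.empty_like(raster.counts)
        for i in range(K):
            shifted[i] = np.roll(raster.counts[i], int(rng.integers(T)))
        surrogates[s], _ = _sta_from_counts(shifted, amps, m)
    lower = np.quantile(surrogates, alpha / 2, axis=0)
    upper = np.quantile(surrogates, 1 - alpha / 2, axis=0)
    significant = bool(((sta.taps < lower) | (sta.taps > upper)).any())
    sta.shuffle_band = np.vstack([lower, upper])
    return ShuffleTestResult(
        sta=sta, lower=lower, upper=upper, significant=significant, alpha=alpha,
        n_shuffles=n_shuffles,
    )
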