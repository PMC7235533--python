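"""Synthetic stimulus and spike-raster generator.

Emulates the study conditions the analysis assumes: a one-hour session of
36 trials x 100 s, sub-threshold electrical white-noise pulses at 25 Hz
(Gaussian amplitudes, mean -800 mV, sd 280 mV), half the trials carrying a
single frozen noise realization interleaved with unique-noise trials, and
Poisson spiking driven by

    mu_ti = exp(b0 + phi_i + x_t.k + rho_t)

with a per-trial drift offset phi (GP over trial index), a linear stimulus
filter k, and an extra per-bin modulation rho (GP over bin index). Counts
per bin are mean counts (the bin width is absorbed into b0).
"""

from __future__ import annotations

import warnings

import numpy as np

from .data import GroundTruth, SpikeRaster, StimulusSet
from .kernels import KernelSpec, kernel_matrix
from .rng import substream

__all__ = [
    "generate_stimulus",
    "draw_ground_truth",
    "simulate_raster",
    "simulate_spike_times",
    "filter_template",
    "n_trials_for_session",
    "RateExplosionError",
    "DEFAULT_PHI_KERNEL",
    "DEFAULT_RHO_KERNEL",
]

#: Study-condition defaults: drift over trials is smooth (length ~5 trials
#: out of 36) with sd 0.5 on the log-rate scale; the extra per-bin
#: modulation is a slow AR(1) with sd 0.4 and lag-one correlation 0.95.
#: Together with the default stimulus drive (sd 0.4) and base rate these
#: keep peak per-bin means within physiological range under the rate cap.
DEFAULT_PHI_KERNEL = KernelSpec("matern", scale=0.5, length=5.0)
DEFAULT_RHO_KERNEL = KernelSpec("ar1", scale=0.4, corr=0.95)


class RateExplosionError(RuntimeError):
    """Simulated per-bin mean exceeded the configured cap."""


def n_trials_for_session(session_s: float = 3600.0, trial_s: float = 100.0) -> int:
    """Number of whole trial blocks in a session (one hour of 100 s blocks -> 36)."""
    return int(session_s // trial_s)


def generate_stimulus(
    n_trials: int,
    n_pulses: int,
    mean_mV: float = -800.0,
    sd_mV: float = 280.0,
    frozen_fraction: float = 0.5,
    seed: int = 0,
    pulse_rate_hz: float = 25.0,
    frozen_first: bool = True,
) -> StimulusSet:
    """Draw a white-noise pulse stimulus with interleaved frozen trials.

    Every other trial (starting with trial 0 when ``frozen_first``) repeats
    one fixed realization until the requested ``frozen_fraction`` is
    reached; the remaining trials each get a fresh draw. Reproducible for a
    given seed.
    """
    if n_trials < 1 or n_pulses < 1:
        raise ValueError("n_trials and n_pulses must be positive counts")
    if sd_mV < 0:
        raise ValueError("sd_mV must be non-negative")
    if not 0.0 <= frozen_fraction <= 1.0:
        raise ValueError("frozen_fraction must lie in [0, 1]")
    rng = substream(seed, "stimulus")
    n_frozen = int(round(frozen_fraction * n_trials))
    is_frozen = np.zeros(n_trials, dtype=bool)
    order = np.arange(n_trials)
    interleave = order if frozen_first else order[::-1]
    # even positions first so frozen and unique trials alternate
    slots = np.concatenate([interleave[::2], interleave[1::2]])
    is_frozen[slots[:n_frozen]] = True

    frozen_row = rng.normal(mean_mV, sd_mV, size=n_pulses)
    amplitudes = np.empty((n_trials, n_pulses))
    for i in range(n_trials):
        if is_frozen[i]:
            amplitudes[i] = frozen_row
        else:
            amplitudes[i] = rng.normal(mean_mV, sd_mV, size=n_pulses)
    rid = np.where(is_frozen, 0, -1)
    return StimulusSet(
        amplitudes=amplitudes,
        is_frozen=is_frozen,
        frozen_realization_id=rid,
        pulse_rate_hz=pulse_rate_hz,
    )


def filter_template(name: str, m: int, norm: float = 1.0) -> np.ndarray:
    """Named stimulus-filter shapes over ``m`` causal taps, scaled to L2 ``norm``.

    ``dog`` is a biphasic difference-of-Gaussians bump (fast positive lobe,
    slower negative rebound), the shape electrical STAs of retinal ganglion
    cells typically take; it is balanced to sum to zero so a non-zero-mean
    stimulus adds no DC term to the rate (b0 alone sets the mean rate).
    ``exp`` is a monophasic decay (not zero-sum). ``zero`` gives an all-zero
    filter.
    """
    if m < 1:
        raise ValueError("m must be a positive count")
    lags = np.arange(m, dtype=float)
    if name == "zero" or norm == 0:
        return np.zeros(m)
    if name == "dog":
        shape = np.exp(-0.5 * ((lags - 3.0) / 1.5) ** 2) - 0.8 * np.exp(
            -0.5 * ((lags - 8.0) / 3.0) ** 2
        )
        shape = shape - shape.mean()
    elif name == "exp":
        shape = np.exp(-lags / 4.0)
    else:
        raise ValueError(f"unknown filter template {name!r} (use 'dog', 'exp' or 'zero')")
    nrm = np.linalg.norm(shape)
    if nrm == 0:  # degenerate at tiny m, e.g. a balanced template with one tap
        return np.zeros(m)
    return norm * shape / nrm


def draw_ground_truth(
    K: int,
    T: int,
    m: int,
    phi_kernel: KernelSpec = DEFAULT_PHI_KERNEL,
    rho_kernel: KernelSpec = DEFAULT_RHO_KERNEL,
    filter_shape: str = "dog",
    filter_norm: float | None = None,
    b0: float | None = None,
    seed: int = 0,
) -> GroundTruth:
    """Draw simulation parameters for one synthetic cell.

    phi is a zero-mean GP over trial index 0..K-1 with ``phi_kernel``; rho a
    zero-mean GP over bin index with ``rho_kernel``; the filter comes from a
    named template scaled to ``filter_norm`` (per-mV L2 norm). Setting a
    kernel scale (or the filter norm) to 0 removes that component exactly.

    The default ``b0`` of log(0.3) gives 0.3 counts per 40 ms bin (7.5 Hz),
    a realistic sub-threshold driven rate; the default filter norm puts the
    stimulus drive at sd 0.4 on the log-rate scale for a 280 mV stimulus sd.
    """
    if K < 1 or T < 1 or m < 1:
        raise ValueError("K, T and m must be positive counts")
    rng = substream(seed, "truth")
    if b0 is None:
        b0 = float(np.log(0.3))
    if filter_norm is None:
        filter_norm = 0.4 / 280.0

    def _gp_draw(spec: KernelSpec, n: int) -> np.ndarray:
        if spec.scale == 0:
            return np.zeros(n)
        cov = kernel_matrix(spec, n)
        try:
            chol = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded by jitter
            raise ValueError("kernel is not positive semi-definite") from exc
        return chol @ rng.standard_normal(n)

    phi = _gp_draw(phi_kernel, K)
    rho = _gp_draw(rho_kernel, T)
    k = filter_template(filter_shape, m, filter_norm)
    meta = {
        "phi_kernel": phi_kernel,
        "rho_kernel": rho_kernel,
        "filter_shape": filter_shape,
        "filter_norm": filter_norm,
        "seed": seed,
    }
    return GroundTruth(b0=b0, phi=phi, filter_k=k, rho=rho, meta=meta)


def _stimulus_drive(amplitudes: np.ndarray, k: np.ndarray, T: int) -> np.ndarray:
    """Per-trial causal convolution of raw amplitudes with the filter.

    Tap j weights the pulse j bins before (and including) the current bin;
    bins with incomplete history are zero-padded.
    """
    K, P = amplitudes.shape
    m = len(k)
    drive = np.zeros((K, T))
    for j in range(m):
        if k[j] == 0:
            continue
        drive[:, j:] += k[j] * amplitudes[:, : T - j]
    return drive


def simulate_raster(
    truth: GroundTruth,
    stimulus: StimulusSet,
    delta_t: float = 0.04,
    seed: int = 0,
    rate_cap: float = 50.0,
) -> SpikeRaster:
    """Draw Poisson spike counts from the ground-truth activation.

    Per-bin means are ``exp(b0 + phi_i + x_t.k + rho_t)`` (mean counts; the
    bin width is absorbed into b0). A mean above ``rate_cap`` counts/bin
    aborts with the offending trial and bin named — physiological rates are
    far below that, so a breach signals runaway parameters.
    """
    K, T = truth.n_trials, truth.n_bins
    if stimulus.n_trials != K:
        raise ValueError(f"stimulus has {stimulus.n_trials} trials, truth expects {K}")
    if stimulus.n_pulses < T:
        raise ValueError("stimulus must supply at least T pulses per trial")
    z = (
        truth.b0
        + truth.phi[:, None]
        + _stimulus_drive(stimulus.amplitudes, truth.filter_k, T)
        + truth.rho[None, :]
    )
    mu = np.exp(z)
    if (mu > rate_cap).any():
        i, t = np.unravel_index(np.argmax(mu), mu.shape)
        raise RateExplosionError(
            f"per-bin mean {mu[i, t]:.3g} exceeds cap {rate_cap} at trial {i}, bin {t}"
        )
    rng = substream(seed, "spikes")
    counts = rng.poisson(mu)
    return SpikeRaster(
        counts=counts,
        delta_t=delta_t,
        trial_ids=np.arange(K),
        is_frozen=stimulus.is_frozen.copy(),
    )


def simulate_spike_times(
    raster: SpikeRaster,
    seed: int = 0,
    dead_fraction: float = 0.0,
    dead_time: float = 0.01,
) -> list[np.ndarray]:
    """Place continuous spike times inside each counted bin.

    Spikes are uniform within the bin; a ``dead_fraction`` of them is
    instead placed inside the first ``dead_time`` seconds after the pulse so
    the dead-time discard of the binning stage can be exercised. With the
    default fraction 0 the times land in [dead_time, delta_t) and re-binning
    reproduces the counts exactly.
    """
    if not 0.0 <= dead_fraction <= 1.0:
        raise ValueError("dead_fraction must lie in [0, 1]")
    rng = substream(seed, "spike_times")
    dt = raster.delta_t
    out: list[np.ndarray] = []
    for i in range(raster.n_trials):
        times = []
        for t in range(raster.n_bins):
            n = raster.counts[i, t]
            if n == 0:
                continue
            in_dead = rng.random(n) < dead_fraction
            u = rng.random(n)
            s = np.where(in_dead, u * dead_time, dead_time + u * (dt - dead_time))
            times.append(t * dt + s)
        out.append(np.sort(np.concatenate(times)) if times else np.empty(0))
    return out
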