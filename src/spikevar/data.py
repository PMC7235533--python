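"""Core in-memory containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = ["StimulusSet", "SpikeRaster", "GroundTruth"]


@dataclass
class StimulusSet:
    """Pulse-amplitude sequences for one recording session.

    ``amplitudes`` is trials x pulses, in mV. Trials flagged frozen share a
    single white-noise realization (identified by ``frozen_realization_id``);
    unique trials carry fresh draws and id -1.
    """

    amplitudes: np.ndarray
    is_frozen: np.ndarray
    frozen_realization_id: np.ndarray
    pulse_rate_hz: float = 25.0
    pulse_width_ms: float = 1.0

    def __post_init__(self) -> None:
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        self.is_frozen = np.asarray(self.is_frozen, dtype=bool)
        self.frozen_realization_id = np.asarray(self.frozen_realization_id, dtype=int)
        if self.amplitudes.ndim != 2:
            raise ValueError("amplitudes must be a trials x pulses matrix")
        k = self.amplitudes.shape[0]
        if self.is_frozen.shape != (k,) or self.frozen_realization_id.shape != (k,):
            raise ValueError("per-trial flags must have one entry per trial")
        if not np.all(np.isfinite(self.amplitudes)):
            raise ValueError("amplitudes must be finite")
        self.validate_frozen_identity()

    @property
    def n_trials(self) -> int:
        return self.amplitudes.shape[0]

    @property
    def n_pulses(self) -> int:
        return self.amplitudes.shape[1]

    def validate_frozen_identity(self) -> None:
        """Frozen trials with the same realization id must be bit-identical."""
        for rid in np.unique(self.frozen_realization_id[self.is_frozen]):
            rows = self.amplitudes[self.is_frozen & (self.frozen_realization_id == rid)]
            if rows.shape[0] > 1 and not (rows == rows[0]).all():
                raise ValueError(f"frozen trials with realization id {rid} differ")

    def frozen_realization(self, rid: int | None = None) -> np.ndarray:
        """Return the shared amplitude sequence of one frozen realization."""
        mask = self.is_frozen
        if rid is not None:
            mask = mask & (self.frozen_realization_id == rid)
        if not mask.any():
            raise ValueError("no frozen trials in this stimulus set")
        return self.amplitudes[mask][0]

    def pulse_times(self) -> np.ndarray:
        """Within-trial pulse timestamps in seconds (regular pulse train)."""
        return np.arange(self.n_pulses) / self.pulse_rate_hz


@dataclass
class SpikeRaster:
    """Binned spike counts, trials x bins, with bin width ``delta_t`` seconds.

    ``trial_ids`` are session trial indices (used as GP inputs for the
    per-trial drift, so that interleaved frozen/unique designs keep their
    real temporal spacing). ``n_dropped_dead``/``n_dropped_range`` audit the
    spikes discarded during binning.
    """

    counts: np.ndarray
    delta_t: float
    trial_ids: np.ndarray | None = None
    is_frozen: np.ndarray | None = None
    dead_time: float = 0.0
    n_dropped_dead: int = 0
    n_dropped_range: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be trials x bins")
        if not np.issubdtype(self.counts.dtype, np.integer):
            rounded = np.rint(self.counts)
            if not np.allclose(self.counts, rounded):
                raise ValueError("counts must be integers")
            self.counts = rounded.astype(np.int64)
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if not self.delta_t > 0:
            raise ValueError("delta_t must be positive")
        k = self.counts.shape[0]
        if self.trial_ids is None:
            self.trial_ids = np.arange(k)
        self.trial_ids = np.asarray(self.trial_ids, dtype=int)
        if self.is_frozen is None:
            self.is_frozen = np.ones(k, dtype=bool)
        self.is_frozen = np.asarray(self.is_frozen, dtype=bool)
        if self.trial_ids.shape != (k,) or self.is_frozen.shape != (k,):
            raise ValueError("per-trial metadata must have one entry per trial")

    @property
    def n_trials(self) -> int:
        return self.counts.shape[0]

    @property
    def n_bins(self) -> int:
        return self.counts.shape[1]

    @property
    def n_spikes(self) -> int:
        return int(self.counts.sum())

    def frozen_subset(self) -> "SpikeRaster":
        """Restrict to the repeating (frozen-noise) trials the models use."""
        m = self.is_frozen
        return SpikeRaster(
            counts=self.counts[m],
            delta_t=self.delta_t,
            trial_ids=self.trial_ids[m],
            is_frozen=self.is_frozen[m],
            dead_time=self.dead_time,
        )


@dataclass
class GroundTruth:
    """Simulation parameters for one synthetic cell.

    ``b0`` is the log mean count per bin; ``phi`` the per-trial drift
    offsets; ``filter_k`` the linear stimulus filter in per-mV units;
    ``rho`` the per-bin modulation shared across trials. ``meta`` records
    the kernel specs and template the draw used.
    """

    b0: float
    phi: np.ndarray
    filter_k: np.ndarray
    rho: np.ndarray
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.phi = np.atleast_1d(np.asarray(self.phi, dtype=float))
        self.filter_k = np.atleast_1d(np.asarray(self.filter_k, dtype=float))
        self.rho = np.atleast_1d(np.asarray(self.rho, dtype=float))
        for name in ("phi", "filter_k", "rho"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"{name} must be finite")
        if not np.isfinite(self.b0):
            raise ValueError("b0 must be finite")

    @property
    def n_trials(self) -> int:
        return len(self.phi)

    @property
    def n_bins(self) -> int:
        return len(self.rho)
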