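"""Model / Results objects tying the pipeline together.

``NestedPoissonGLM`` holds one cell's data (binned raster + stimulus) and
the modelling conventions (filter length, Matérn smoothness,
standardization). ``fit()`` runs the sequential cross-validated
hyper-parameter search with the collapse rule and returns a
``NestedGLMResults`` carrying the selected hyper-parameters, per-level
cross-validated and training log-likelihoods, refit parameters, and the
train/cv variance partitions, with a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import SpikeRaster, StimulusSet
from .design import StimulusDesign, build_design
from .glm import LEVELS, ModelParams
from .partition import PartitionResult, evaluate_hierarchy
from .partition import _train_refit  # shared refit logic
from .selection import DEFAULT_GRIDS, FoldSpec, GridSpec, SelectionResult, make_folds, select_sequential

__all__ = ["NestedPoissonGLM", "NestedGLMResults"]


class NestedPoissonGLM:
    """Nested Poisson GLM hierarchy for one cell.

    Parameters
    ----------
    raster : SpikeRaster
        Binned spike counts. Only the repeating (frozen-noise) trials are
        used for fitting; unique-noise trials are dropped on construction.
    stimulus : StimulusSet, optional
        Pulse amplitudes; required for the filter (NS-LNP) level. Without
        it the hierarchy stops at NS-PSTH with no stimulus drive.
    m : int
        Filter length in taps (bins of history, lag 0 = own bin).
    standardize : bool
        Z-score the stimulus before building the design (default), so
        filter taps and their prior live on an order-one scale.
    history : {"pad", "drop"}
        Handling of the first m-1 bins with incomplete stimulus history.
    matern_nu : float
        Matérn smoothness of the drift/filter priors.
    """

    def __init__(
        self,
        raster: SpikeRaster,
        stimulus: StimulusSet | None = None,
        m: int = 25,
        standardize: bool = True,
        history: str = "pad",
        matern_nu: float = 1.5,
        cell_id: str | None = None,
        cell_type: str | None = None,
    ) -> None:
        if not raster.is_frozen.any():
            raise ValueError("no repeating (frozen) trials to fit on")
        self.raster_full = raster
        self.raster = raster.frozen_subset()
        self.stimulus = stimulus
        self.m = m
        self.matern_nu = matern_nu
        self.cell_id = cell_id
        self.cell_type = cell_type
        if stimulus is not None:
            self.design: StimulusDesign | None = build_design(
                stimulus, m=m, n_bins=self.raster.n_bins,
                standardize=standardize, history=history,
            )
        else:
            self.design = None

    @classmethod
    def from_spike_times(
        cls,
        spike_times,
        stimulus: StimulusSet,
        delta_t: float = 0.04,
        dead_time: float = 0.01,
        **kwargs,
    ) -> "NestedPoissonGLM":
        """Build the model straight from per-trial spike times."""
        from .preprocess import bin_spikes

        pulse_times = [stimulus.pulse_times()] * stimulus.n_trials
        raster = bin_spikes(
            spike_times, pulse_times, delta_t=delta_t, dead_time=dead_time,
            is_frozen=stimulus.is_frozen,
        )
        return cls(raster, stimulus, **kwargs)

    def fit(
        self,
        grids: dict[str, GridSpec] | None = None,
        folds: FoldSpec | None = None,
        n_folds: int = 10,
        seed: int = 0,
    ) -> "NestedGLMResults":
        """Run the sequential CV search and evaluate the partition."""
        if grids is None:
            grids = {
                lv: (
                    GridSpec(g.family, g.scales, g.lengths, g.corrs, nu=self.matern_nu)
                    if g.family == "matern"
                    else g
                )
                for lv, g in DEFAULT_GRIDS.items()
            }
        selection = select_sequential(
            self.raster, self.design, grids=grids, folds=folds, n_folds=n_folds, seed=seed
        )
        meta = {"cell_id": self.cell_id, "cell_type": self.cell_type}
        part_cv = evaluate_hierarchy(selection, self.raster, self.design, "cv", **meta)
        part_train = evaluate_hierarchy(selection, self.raster, self.design, "train", **meta)
        params = _train_refit(selection, self.raster, self.design)
        return NestedGLMResults(
            model=self,
            selection=selection,
            params=params,
            partition_cv=part_cv,
            partition_train=part_train,
        )


@dataclass
class NestedGLMResults:
    """Fitted hierarchy for one cell."""

    model: NestedPoissonGLM
    selection: SelectionResult
    params: dict[str, ModelParams]
    partition_cv: PartitionResult
    partition_train: PartitionResult

    def partition(self, evaluation: str = "cv") -> PartitionResult:
        if evaluation == "cv":
            return self.partition_cv
        if evaluation == "train":
            return self.partition_train
        raise ValueError("evaluation must be 'train' or 'cv'")

    @property
    def cvll(self) -> dict[str, float]:
        return dict(self.selection.cvll)

    def predicted_rate(self, level: str = "NS-PSTH") -> np.ndarray:
        """Predicted firing rate (Hz) per trial and bin at the given level."""
        from .glm import activation_matrix

        p = self.params[level]
        r = self.model.raster
        z = activation_matrix(p, self.model.design, r.n_trials, r.n_bins)
        return np.exp(np.broadcast_to(z, r.counts.shape)) / r.delta_t

    def level_table(self) -> pd.DataFrame:
        rows = []
        for lv in LEVELS:
            hyper = self.selection.best_hyper.get(lv)
            rows.append(
                {
                    "level": lv,
                    "cvll": self.selection.cvll[lv],
                    "collapsed": self.selection.collapsed.get(lv, False),
                    "scale": getattr(hyper, "scale", np.nan),
                    "length_or_corr": (
                        hyper.length if hyper is not None and hyper.family == "matern"
                        else getattr(hyper, "corr", np.nan)
                    ),
                }
            )
        return pd.DataFrame(rows).set_index("level")

    def summary(self) -> str:
        """Human-readable fit summary."""
        r = self.model.raster
        pc, pt = self.partition_cv, self.partition_train
        rate_hz = r.n_spikes / (r.counts.size * r.delta_t)
        lines = [
            "Nested Poisson GLM hierarchy",
            "=" * 64,
            f"cell: {self.model.cell_id or '-'}    type: {self.model.cell_type or '-'}",
            f"repeating trials: {r.n_trials}   bins/trial: {r.n_bins}   "
            f"dt: {r.delta_t * 1e3:.0f} ms",
            f"spikes: {r.n_spikes}   mean rate: {rate_hz:.2f} Hz",
            "",
            "Level      CVLL           collapsed  scale   length/corr",
            "-" * 64,
        ]
        for lv, row in self.level_table().iterrows():
            lines.append(
                f"{lv:<10} {row['cvll']:<14.2f} {str(bool(row['collapsed'])):<10} "
                f"{row['scale'] if np.isfinite(row['scale']) else '-':<7} "
                f"{row['length_or_corr'] if np.isfinite(row['length_or_corr']) else '-'}"
            )
        lines += [
            "-" * 64,
            "Partition of explainable log-likelihood gain (fraction of L_sat - L_BS)",
            f"{'':14}{'cv':>10}{'train':>10}",
        ]
        for name, a, b in (
            ("nonstationary", pc.P_nonstat, pt.P_nonstat),
            ("linear", pc.P_lin, pt.P_lin),
            ("nonlinear", pc.P_nonlin, pt.P_nonlin),
            ("signal", pc.P_sig, pt.P_sig),
            ("unexplained", pc.P_noise, pt.P_noise),
        ):
            lines.append(f"{name:<14}{a:>10.3f}{b:>10.3f}")
        return "\n".join(lines)
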