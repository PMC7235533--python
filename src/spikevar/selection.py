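"""Trial-level 10-fold cross-validation and sequential hyper-parameter choice.

The hierarchy is grown one level at a time (NS, then NS-LNP, then
NS-PSTH). At each level a grid of GP hyper-parameters is scored by
cross-validated log-likelihood (CVLL): on each fold the new block is
MAP-fitted on the training trials with every earlier block frozen at the
values it took on that same fold under the previous level's winning
hyper-parameters, and the fit is scored on the held-out trials. Folds are
drawn once over the repeating (frozen-noise) trials and reused for every
level and grid point.

Collapse rule: every grid contains the scale-0 point, which reproduces the
previous level exactly; if the best new CVLL is below the previous level's
the level collapses (parameters zeroed, CVLL copied). Reported CVLL is
therefore non-decreasing across the hierarchy by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .data import SpikeRaster
from .design import StimulusDesign
from .glm import ModelParams, fit_baseline, fit_map_block, poisson_loglik, predict_phi
from .kernels import KernelSpec
from .rng import substream

__all__ = [
    "FoldSpec",
    "GridSpec",
    "FoldState",
    "SelectionResult",
    "make_folds",
    "cv_score",
    "select_sequential",
    "DEFAULT_GRIDS",
]

_LEVEL_BLOCK = {"NS": "phi", "NS-LNP": "k", "NS-PSTH": "rho"}


@dataclass(frozen=True)
class FoldSpec:
    """A partition of trial positions into held-out sets."""

    held_out: tuple[tuple[int, ...], ...]
    seed: int

    @property
    def n_folds(self) -> int:
        return len(self.held_out)

    def train(self, f: int, n_trials: int) -> np.ndarray:
        test = set(self.held_out[f])
        return np.array([i for i in range(n_trials) if i not in test], dtype=int)

    def test(self, f: int) -> np.ndarray:
        return np.asarray(self.held_out[f], dtype=int)


@dataclass(frozen=True)
class GridSpec:
    """Candidate GP hyper-parameters for one level.

    ``scales`` always includes 0, the collapse point; for the matern family
    the grid is scales x lengths, for ar1 scales x corrs.
    """

    family: str
    scales: tuple[float, ...]
    lengths: tuple[float, ...] = ()
    corrs: tuple[float, ...] = ()
    nu: float = 1.5

    def __post_init__(self) -> None:
        if self.family not in ("matern", "ar1"):
            raise ValueError("family must be 'matern' or 'ar1'")
        if len(self.scales) == 0:
            raise ValueError("grid must be non-empty")
        if 0.0 not in self.scales:
            object.__setattr__(self, "scales", (0.0,) + tuple(self.scales))
        second = self.lengths if self.family == "matern" else self.corrs
        if len(second) == 0:
            raise ValueError(f"grid needs {'lengths' if self.family == 'matern' else 'corrs'}")

    def points(self) -> list[KernelSpec]:
        """Grid points, most regularized first (scale asc, then length/corr asc)."""
        pts: list[KernelSpec] = []
        for s in sorted(self.scales):
            if s == 0.0:
                # one collapse point is enough; second hyper is irrelevant
                if self.family == "matern":
                    pts.append(KernelSpec("matern", 0.0, length=sorted(self.lengths)[0], nu=self.nu))
                else:
                    pts.append(KernelSpec("ar1", 0.0, corr=sorted(self.corrs)[0]))
                continue
            if self.family == "matern":
                pts.extend(
                    KernelSpec("matern", s, length=t, nu=self.nu) for t in sorted(self.lengths)
                )
            else:
                pts.extend(KernelSpec("ar1", s, corr=a) for a in sorted(self.corrs))
        return pts


#: Log-spaced default grids; trial units for the NS length, tap units for
#: the filter length, lag-one correlation for the per-bin modulation.
DEFAULT_GRIDS: dict[str, GridSpec] = {
    "NS": GridSpec("matern", (0.0, 0.03, 0.1, 0.3, 1.0, 3.0), lengths=(0.5, 1, 2, 5, 10, 20)),
    "NS-LNP": GridSpec("matern", (0.0, 0.03, 0.1, 0.3, 1.0, 3.0), lengths=(0.5, 1, 2, 5, 10, 20)),
    "NS-PSTH": GridSpec(
        "ar1", (0.0, 0.03, 0.1, 0.3, 1.0, 3.0), corrs=(0.0, 0.3, 0.6, 0.8, 0.9, 0.95, 0.99)
    ),
}


@dataclass
class FoldState:
    """Everything one fold carries forward through the hierarchy."""

    train: np.ndarray
    test: np.ndarray
    b0: float = 0.0
    phi_train: np.ndarray | None = None
    phi_test: np.ndarray | None = None
    k: np.ndarray | None = None
    rho: np.ndarray | None = None

    def params_for(self, idx: np.ndarray, m: int, T: int, which: str = "train") -> ModelParams:
        """Assemble ModelParams for the given trial positions."""
        phi = self.phi_train if which == "train" else self.phi_test
        K = len(idx)
        return ModelParams(
            b0=self.b0,
            phi=np.zeros(K) if phi is None else phi,
            k=np.zeros(m) if self.k is None else self.k,
            rho=np.zeros(T) if self.rho is None else self.rho,
        )


@dataclass
class SelectionResult:
    """Outcome of the sequential CV search for one cell."""

    folds: FoldSpec
    cvll: dict[str, float]
    per_fold_cvll: dict[str, np.ndarray]
    best_hyper: dict[str, KernelSpec | None]
    collapsed: dict[str, bool]
    grid_tables: dict[str, pd.DataFrame]
    fold_states: list[FoldState]

    def __post_init__(self) -> None:
        levels = ["BS", "NS", "NS-LNP", "NS-PSTH"]
        vals = [self.cvll[lv] for lv in levels if lv in self.cvll]
        if any(b < a - 1e-9 for a, b in zip(vals, vals[1:])):
            raise AssertionError(f"CVLL must be non-decreasing across levels, got {vals}")


def make_folds(trial_positions: np.ndarray | list[int], n_folds: int = 10, seed: int = 0) -> FoldSpec:
    """Partition trial positions into folds holding out one or two trials.

    Trials are shuffled once and dealt round-robin, so with 18 repeating
    trials and 10 folds, 8 folds hold out 2 trials and 2 folds hold out 1.
    Deterministic for a given seed.
    """
    positions = np.asarray(trial_positions, dtype=int)
    if n_folds < 1:
        raise ValueError("n_folds must be >= 1")
    if len(positions) < n_folds:
        raise ValueError(f"{len(positions)} trials cannot fill {n_folds} folds")
    rng = substream(seed, "folds")
    shuffled = rng.permutation(positions)
    held = tuple(tuple(int(x) for x in shuffled[f::n_folds]) for f in range(n_folds))
    return FoldSpec(held_out=held, seed=seed)


def _subraster(raster: SpikeRaster, idx: np.ndarray) -> SpikeRaster:
    return SpikeRaster(
        counts=raster.counts[idx],
        delta_t=raster.delta_t,
        trial_ids=raster.trial_ids[idx],
        is_frozen=raster.is_frozen[idx],
        dead_time=raster.dead_time,
    )


def _baseline_cv(raster: SpikeRaster, design: StimulusDesign | None, folds: FoldSpec):
    """Per-fold training-mean baseline and its held-out log-likelihood."""
    m = design.m if design is not None else 1
    T = raster.n_bins
    mask = design.bin_mask if design is not None else None
    states, cvlls = [], []
    for f in range(folds.n_folds):
        tr, te = folds.train(f, raster.n_trials), folds.test(f)
        base = fit_baseline(_subraster(raster, tr), design, bin_mask=mask)
        st = FoldState(train=tr, test=te, b0=base.b0)
        p_test = st.params_for(te, m, T, "test")
        cvlls.append(poisson_loglik(p_test, _subraster(raster, te), design, bin_mask=mask))
        states.append(st)
    return states, np.array(cvlls)


def cv_score(
    level: str,
    hyper: KernelSpec,
    folds: FoldSpec,
    raster: SpikeRaster,
    design: StimulusDesign | None,
    fixed_per_fold: list[FoldState],
) -> tuple[float, np.ndarray, list[FoldState]]:
    """Cross-validated log-likelihood of one hyper-parameter point.

    For each fold, fits the level's new block on the training trials with
    the earlier blocks frozen at that fold's previous-level values, then
    scores the held-out trials. Returns (mean CVLL, per-fold CVLL, the
    candidate per-fold states carrying the new block).
    """
    block = _LEVEL_BLOCK[level]
    m = design.m if design is not None else 1
    T = raster.n_bins
    mask = design.bin_mask if design is not None else None
    cvlls, states = [], []
    for f, st in enumerate(fixed_per_fold):
        tr, te = st.train, st.test
        sub_tr = _subraster(raster, tr)
        fixed = st.params_for(tr, m, T, "train")
        try:
            fitted = fit_map_block(
                sub_tr, design, fixed, block, hyper,
                bin_mask=mask, trial_index=raster.trial_ids[tr],
            )
        except Exception as exc:
            raise RuntimeError(f"fold {f}: fit of {level} at {hyper} failed") from exc
        new = replace(st)
        if block == "phi":
            new.phi_train = fitted.phi
            new.phi_test = predict_phi(
                fitted.phi, raster.trial_ids[tr], raster.trial_ids[te], hyper
            )
        elif block == "k":
            new.k = fitted.k
        else:
            new.rho = fitted.rho
        p_test = new.params_for(te, m, T, "test")
        cvlls.append(poisson_loglik(p_test, _subraster(raster, te), design, bin_mask=mask))
        states.append(new)
    arr = np.array(cvlls)
    return float(arr.mean()), arr, states


def select_sequential(
    raster: SpikeRaster,
    design: StimulusDesign | None,
    grids: dict[str, GridSpec] | None = None,
    folds: FoldSpec | None = None,
    n_folds: int = 10,
    seed: int = 0,
) -> SelectionResult:
    """Run the full sequential CV protocol on the repeating trials.

    Levels are optimized in order NS -> NS-LNP -> NS-PSTH; at each level
    the argmax-CVLL grid point is frozen (per fold) before the next level
    is searched. Ties prefer the most regularized point (smallest scale,
    then smallest length/corr). A level whose best CVLL does not beat the
    previous level collapses to it.
    """
    if raster.n_trials < 1:
        raise ValueError("raster has no trials")
    if not raster.is_frozen.all():
        raster = raster.frozen_subset()  # only repeating trials are modelled
    grids = dict(DEFAULT_GRIDS) if grids is None else grids
    if folds is None:
        folds = make_folds(np.arange(raster.n_trials), n_folds=n_folds, seed=seed)

    states, bs_cvll = _baseline_cv(raster, design, folds)
    cvll = {"BS": float(bs_cvll.mean())}
    per_fold = {"BS": bs_cvll}
    best_hyper: dict[str, KernelSpec | None] = {"BS": None}
    collapsed = {"BS": False}
    tables: dict[str, pd.DataFrame] = {}

    for level in ("NS", "NS-LNP", "NS-PSTH"):
        prev = cvll[list(cvll)[-1]]
        if level == "NS-LNP" and design is None:
            # no stimulus: the filter level cannot improve and collapses
            cvll[level] = prev
            per_fold[level] = per_fold[list(per_fold)[-1]]
            collapsed[level] = True
            best_hyper[level] = None
            tables[level] = pd.DataFrame()
            continue
        rows = []
        best = None  # (mean, per_fold, states, hyper)
        for point in grids[level].points():
            if point.scale == 0.0:
                mean, arr, cand = prev, per_fold[list(per_fold)[-1]], states
            else:
                mean, arr, cand = cv_score(level, point, folds, raster, design, states)
            rows.append(
                {
                    "scale": point.scale,
                    ("length" if point.family == "matern" else "corr"):
                        point.length if point.family == "matern" else point.corr,
                    "cvll": mean,
                }
            )
            if best is None or mean > best[0]:  # strict: first (most regularized) wins ties
                best = (mean, arr, cand, point)
        mean, arr, cand, point = best
        tables[level] = pd.DataFrame(rows)
        if mean <= prev or point.scale == 0.0:
            # collapse: copy the previous level's CVLL, pin the block to zero
            cvll[level] = prev
            per_fold[level] = per_fold[list(per_fold)[-1]]
            collapsed[level] = True
            best_hyper[level] = None
            # states unchanged: the new block stays at its zero default
        else:
            cvll[level] = mean
            per_fold[level] = arr
            collapsed[level] = False
            best_hyper[level] = point
            states = cand

    return SelectionResult(
        folds=folds,
        cvll=cvll,
        per_fold_cvll=per_fold,
        best_hyper=best_hyper,
        collapsed=collapsed,
        grid_tables=tables,
        fold_states=states,
    )
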