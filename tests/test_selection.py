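"""Fold construction, CV scoring, sequential selection and the collapse rule."""

import numpy as np
import pytest

from spikevar import (
    GridSpec,
    KernelSpec,
    draw_ground_truth,
    generate_stimulus,
    make_folds,
    simulate_raster,
    build_design,
    fit_baseline,
    poisson_loglik,
)
from spikevar.glm import ModelParams
from spikevar.selection import select_sequential
from spikevar.data import SpikeRaster

from conftest import small_grids


class TestMakeFolds:
    def test_18_trials_10_folds_hold_out_one_or_two(self):
        folds = make_folds(np.arange(18), n_folds=10, seed=0)
        sizes = sorted(len(f) for f in folds.held_out)
        assert sizes == [1, 1, 2, 2, 2, 2, 2, 2, 2, 2]
        # a proper partition: every trial held out exactly once
        allout = sorted(t for f in folds.held_out for t in f)
        assert allout == list(range(18))

    def test_same_seed_reproduces_folds(self):
        assert make_folds(np.arange(18), 10, seed=3) == make_folds(np.arange(18), 10, seed=3)
        assert make_folds(np.arange(18), 10, seed=3) != make_folds(np.arange(18), 10, seed=4)

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError):
            make_folds(np.arange(5), n_folds=10, seed=0)


def _sim(seed, K=8, T=300, **truth_kw):
    stim = generate_stimulus(K, T, frozen_fraction=1.0, seed=seed)
    truth = draw_ground_truth(K=K, T=T, m=8, seed=seed, **truth_kw)
    raster = simulate_raster(truth, stim, seed=seed)
    return raster, stim, truth


class TestSelectSequential:
    def test_baseline_cvll_matches_direct_computation(self):
        raster, stim, _ = _sim(0)
        design = build_design(stim, m=8)
        sel = select_sequential(raster, design, grids=small_grids(), n_folds=4, seed=1)
        # oracle: per fold, training-mean model scored on held-out trials
        vals = []
        for f in range(4):
            te = sel.folds.test(f)
            tr = sel.folds.train(f, raster.n_trials)
            b0 = np.log(raster.counts[tr].mean())
            sub = SpikeRaster(counts=raster.counts[te], delta_t=raster.delta_t)
            p = ModelParams.zeros(len(te), 8, raster.n_bins, b0=b0)
            vals.append(poisson_loglik(p, sub))
        assert sel.cvll["BS"] == pytest.approx(np.mean(vals), abs=1e-9)

    def test_collapse_point_reproduces_previous_level(self):
        raster, stim, _ = _sim(1)
        design = build_design(stim, m=8)
        zero_grids = {
            "NS": GridSpec("matern", (0.0,), lengths=(5.0,)),
            "NS-LNP": GridSpec("matern", (0.0,), lengths=(5.0,)),
            "NS-PSTH": GridSpec("ar1", (0.0,), corrs=(0.9,)),
        }
        sel = select_sequential(raster, design, grids=zero_grids, n_folds=4, seed=1)
        assert sel.cvll["NS"] == sel.cvll["BS"]
        assert sel.cvll["NS-PSTH"] == sel.cvll["BS"]
        assert all(sel.collapsed[lv] for lv in ("NS", "NS-LNP", "NS-PSTH"))

    def test_cvll_is_monotone_and_deterministic(self):
        raster, stim, _ = _sim(2)
        design = build_design(stim, m=8)
        a = select_sequential(raster, design, grids=small_grids(), n_folds=4, seed=7)
        b = select_sequential(raster, design, grids=small_grids(), n_folds=4, seed=7)
        levels = ["BS", "NS", "NS-LNP", "NS-PSTH"]
        vals = [a.cvll[lv] for lv in levels]
        assert all(y >= x for x, y in zip(vals, vals[1:]))
        assert a.cvll == b.cvll
        for lv in levels:
            assert (a.per_fold_cvll[lv] == b.per_fold_cvll[lv]).all()
        for sa, sb in zip(a.fold_states, b.fold_states):
            assert sa.b0 == sb.b0
            for attr in ("phi_train", "phi_test", "k", "rho"):
                va, vb = getattr(sa, attr), getattr(sb, attr)
                assert (va is None and vb is None) or (va == vb).all()

    def test_single_point_grids_still_run(self):
        raster, stim, _ = _sim(3, K=6, T=200)
        design = build_design(stim, m=8)
        grids = {
            "NS": GridSpec("matern", (0.0, 0.5), lengths=(5.0,)),
            "NS-LNP": GridSpec("matern", (0.0, 0.5), lengths=(5.0,)),
            "NS-PSTH": GridSpec("ar1", (0.0, 0.5), corrs=(0.9,)),
        }
        sel = select_sequential(raster, design, grids=grids, n_folds=3, seed=2)
        assert set(sel.cvll) == {"BS", "NS", "NS-LNP", "NS-PSTH"}

    def test_enlarging_a_grid_never_decreases_selected_cvll(self):
        raster, stim, _ = _sim(4)
        design = build_design(stim, m=8)
        small = {
            "NS": GridSpec("matern", (0.0, 0.3), lengths=(5.0,)),
            "NS-LNP": GridSpec("matern", (0.0,), lengths=(5.0,)),
            "NS-PSTH": GridSpec("ar1", (0.0,), corrs=(0.9,)),
        }
        big = dict(small)
        big["NS"] = GridSpec("matern", (0.0, 0.1, 0.3, 1.0), lengths=(2.0, 5.0, 10.0))
        sel_small = select_sequential(raster, design, grids=small, n_folds=4, seed=9)
        sel_big = select_sequential(raster, design, grids=big, n_folds=4, seed=9)
        assert sel_big.cvll["NS"] >= sel_small.cvll["NS"] - 1e-12

    def test_no_stimulus_collapses_filter_level(self):
        raster, _, _ = _sim(5, K=6, T=200)
        sel = select_sequential(raster, None, grids=small_grids(), n_folds=3, seed=5)
        assert sel.collapsed["NS-LNP"]
        assert sel.cvll["NS-LNP"] == sel.cvll["NS"]

    def test_strong_truth_selects_all_levels(self, fitted_cell):
        res, _ = fitted_cell
        sel = res.selection
        assert not any(sel.collapsed[lv] for lv in ("NS", "NS-LNP", "NS-PSTH"))
        vals = [sel.cvll[lv] for lv in ("BS", "NS", "NS-LNP", "NS-PSTH")]
        assert all(y > x for x, y in zip(vals, vals[1:]))

    def test_drift_only_rarely_finds_stimulus_structure(self, drift_sweep):
        # with no stimulus dependence in the truth, the filter and per-bin
        # levels should collapse or add next to nothing in most seeds
        near_zero = 0
        for res in drift_sweep:
            sel = res.selection
            denom = res.partition_cv.L_sat - res.partition_cv.L_BS
            gain = (sel.cvll["NS-PSTH"] - sel.cvll["NS"]) / denom
            if (sel.collapsed["NS-LNP"] and sel.collapsed["NS-PSTH"]) or gain < 0.01:
                near_zero += 1
        assert near_zero > len(drift_sweep) / 2
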