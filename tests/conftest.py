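"""Shared fixtures: toy rasters and session-scoped simulation sweeps."""

from __future__ import annotations

import numpy as np
import pytest

from spikevar import (
    GridSpec,
    KernelSpec,
    NestedPoissonGLM,
    SpikeRaster,
    draw_ground_truth,
    generate_stimulus,
    simulate_raster,
)
from spikevar.selection import select_sequential
from spikevar.partition import evaluate_hierarchy


def small_grids() -> dict[str, GridSpec]:
    """Reduced hyper-parameter grids for test-scale runs (collapse point included)."""
    return {
        "NS": GridSpec("matern", (0.0, 0.1, 0.3, 1.0), lengths=(2.0, 5.0)),
        "NS-LNP": GridSpec("matern", (0.0, 0.1, 0.3, 1.0), lengths=(2.0, 5.0)),
        "NS-PSTH": GridSpec("ar1", (0.0, 0.1, 0.3, 1.0), corrs=(0.6, 0.95)),
    }


@pytest.fixture(scope="session")
def grids():
    return small_grids()


@pytest.fixture
def tiny_raster() -> SpikeRaster:
    counts = np.array([[0, 1, 2, 0], [1, 0, 3, 1], [0, 0, 0, 2]])
    return SpikeRaster(counts=counts, delta_t=0.04)


def _run_cell(truth_kw: dict, seed: int, grids: dict, n_trials: int = 18,
              frozen_fraction: float = 1.0):
    stim = generate_stimulus(n_trials, 2500, frozen_fraction=frozen_fraction, seed=seed)
    truth = draw_ground_truth(K=n_trials, T=2500, m=25, seed=seed, **truth_kw)
    raster = simulate_raster(truth, stim, seed=seed)
    glm = NestedPoissonGLM(raster, stim, m=25)
    return glm.fit(grids=grids, seed=seed), truth


@pytest.fixture(scope="session")
def fitted_cell(grids):
    """One cell simulated from the full hierarchy (drift + filter + per-bin
    modulation) at study scale, fitted end to end."""
    res, truth = _run_cell({}, seed=11, grids=grids, n_trials=36, frozen_fraction=0.5)
    return res, truth


@pytest.fixture(scope="session")
def null_sweep(grids):
    """50 stationary stimulus-independent cells (constant-rate Poisson) at
    K=18 repeating trials x T=2500 bins, fitted end to end."""
    null_truth = dict(
        phi_kernel=KernelSpec("matern", 0.0, length=5.0),
        rho_kernel=KernelSpec("ar1", 0.0, corr=0.95),
        filter_norm=0.0,
    )
    out = []
    for seed in range(50):
        res, _ = _run_cell(null_truth, seed=seed, grids=grids)
        out.append(res)
    return out


@pytest.fixture(scope="session")
def drift_sweep(grids):
    """15 drift-only cells (strong non-stationarity, no stimulus dependence)."""
    truth_kw = dict(
        phi_kernel=KernelSpec("matern", 1.0, length=5.0),
        rho_kernel=KernelSpec("ar1", 0.0, corr=0.95),
        filter_norm=0.0,
    )
    out = []
    for seed in range(100, 115):
        res, _ = _run_cell(truth_kw, seed=seed, grids=grids)
        out.append(res)
    return out


@pytest.fixture(scope="session")
def toy_fit(grids):
    """A fast small-scale fitted cell for API-level tests."""
    stim = generate_stimulus(8, 400, frozen_fraction=1.0, seed=5)
    truth = draw_ground_truth(K=8, T=400, m=10, seed=5)
    raster = simulate_raster(truth, stim, seed=5)
    glm = NestedPoissonGLM(raster, stim, m=10)
    return glm.fit(grids=grids, n_folds=4, seed=5), truth, stim, raster
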