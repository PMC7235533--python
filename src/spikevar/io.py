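"""File formats, configuration, and the end-to-end pipeline.

All interchange is plain text: comma-separated, UTF-8, header row, '.'
decimal; times in seconds, amplitudes in mV. Rasters can also be stored as
HDF5. Every pipeline output carries the config hash, seed and package
version for provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .data import GroundTruth, SpikeRaster, StimulusSet
from .glm import ModelParams
from .kernels import KernelSpec
from .partition import GroupSummary, PartitionResult, group_summary
from .selection import GridSpec

__all__ = [
    "PipelineConfig",
    "load_config",
    "write_stimulus_csv",
    "read_stimulus_csv",
    "write_spike_times_csv",
    "read_spike_times_csv",
    "write_raster_csv",
    "read_raster_csv",
    "write_raster_hdf5",
    "read_raster_hdf5",
    "write_ground_truth_json",
    "read_ground_truth_json",
    "write_params_json",
    "read_params_json",
    "write_partition_json",
    "run_pipeline",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# stimulus / spike-time CSV


def write_stimulus_csv(stimulus: StimulusSet, path: str | Path) -> None:
    K, P = stimulus.amplitudes.shape
    trial = np.repeat(np.arange(K), P)
    df = pd.DataFrame(
        {
            "trial": trial,
            "pulse": np.tile(np.arange(P), K),
            "amplitude_mV": stimulus.amplitudes.ravel(),
            "is_frozen": np.repeat(stimulus.is_frozen.astype(int), P),
            "realization_id": np.repeat(stimulus.frozen_realization_id, P),
        }
    )
    df.to_csv(path, index=False)


def read_stimulus_csv(path: str | Path, pulse_rate_hz: float = 25.0) -> StimulusSet:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"stimulus file not found: {path}")
    df = pd.read_csv(path)
    trials = np.sort(df["trial"].unique())
    pivot = df.pivot(index="trial", columns="pulse", values="amplitude_mV").loc[trials]
    per_trial = df.drop_duplicates("trial").set_index("trial").loc[trials]
    is_frozen = (
        per_trial["is_frozen"].to_numpy(dtype=bool)
        if "is_frozen" in df.columns
        else np.zeros(len(trials), dtype=bool)
    )
    rid = (
        per_trial["realization_id"].to_numpy(dtype=int)
        if "realization_id" in df.columns
        else np.where(is_frozen, 0, -1)
    )
    return StimulusSet(
        amplitudes=pivot.to_numpy(dtype=float),
        is_frozen=is_frozen,
        frozen_realization_id=rid,
        pulse_rate_hz=pulse_rate_hz,
    )


def write_spike_times_csv(spike_times: list[np.ndarray], path: str | Path) -> None:
    rows = [(i, t) for i, times in enumerate(spike_times) for t in times]
    pd.DataFrame(rows, columns=["trial", "time_s"]).to_csv(path, index=False)


def read_spike_times_csv(path: str | Path, n_trials: int | None = None) -> list[np.ndarray]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"spike-time file not found: {path}")
    df = pd.read_csv(path)
    if n_trials is None:
        n_trials = int(df["trial"].max()) + 1 if len(df) else 0
    return [
        np.sort(df.loc[df["trial"] == i, "time_s"].to_numpy(dtype=float))
        for i in range(n_trials)
    ]


# ---------------------------------------------------------------------------
# raster CSV / HDF5


def write_raster_csv(raster: SpikeRaster, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            f"# delta_t={raster.delta_t!r},dead_time={raster.dead_time!r},"
            f"n_dropped_dead={raster.n_dropped_dead},n_dropped_range={raster.n_dropped_range}\n"
        )
        df = pd.DataFrame(raster.counts, columns=[f"bin{t}" for t in range(raster.n_bins)])
        df.insert(0, "trial_id", raster.trial_ids)
        df.insert(1, "is_frozen", raster.is_frozen.astype(int))
        df.to_csv(fh, index=False)


def read_raster_csv(path: str | Path) -> SpikeRaster:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"raster file not found: {path}")
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().lstrip("# ").strip()
        meta = dict(kv.split("=") for kv in header.split(","))
        df = pd.read_csv(fh)
    bins = [c for c in df.columns if c.startswith("bin")]
    return SpikeRaster(
        counts=df[bins].to_numpy(dtype=np.int64),
        delta_t=float(meta["delta_t"]),
        trial_ids=df["trial_id"].to_numpy(dtype=int),
        is_frozen=df["is_frozen"].to_numpy(dtype=bool),
        dead_time=float(meta.get("dead_time", 0.0)),
        n_dropped_dead=int(meta.get("n_dropped_dead", 0)),
        n_dropped_range=int(meta.get("n_dropped_range", 0)),
    )


def write_raster_hdf5(raster: SpikeRaster, path: str | Path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("counts", data=raster.counts)
        f.create_dataset("trial_ids", data=raster.trial_ids)
        f.create_dataset("is_frozen", data=raster.is_frozen)
        f.attrs["delta_t"] = raster.delta_t
        f.attrs["dead_time"] = raster.dead_time


def read_raster_hdf5(path: str | Path) -> SpikeRaster:
    import h5py

    with h5py.File(path, "r") as f:
        return SpikeRaster(
            counts=f["counts"][()],
            delta_t=float(f.attrs["delta_t"]),
            trial_ids=f["trial_ids"][()],
            is_frozen=f["is_frozen"][()],
            dead_time=float(f.attrs["dead_time"]),
        )


# ---------------------------------------------------------------------------
# JSON artifacts


def _kernel_to_dict(spec: KernelSpec | None) -> dict | None:
    return None if spec is None else dataclasses.asdict(spec)


def _kernel_from_dict(d: dict | None) -> KernelSpec | None:
    return None if d is None else KernelSpec(**d)


def write_ground_truth_json(truth: GroundTruth, path: str | Path) -> None:
    meta = {
        k: (_kernel_to_dict(v) if isinstance(v, KernelSpec) else v)
        for k, v in truth.meta.items()
    }
    payload = {
        "b0": truth.b0,
        "phi": truth.phi.tolist(),
        "filter_k": truth.filter_k.tolist(),
        "rho": truth.rho.tolist(),
        "meta": meta,
    }
    Path(path).write_text(json.dumps(payload), encoding="utf-8")


def read_ground_truth_json(path: str | Path) -> GroundTruth:
    d = json.loads(Path(path).read_text(encoding="utf-8"))
    meta = {
        k: (_kernel_from_dict(v) if k.endswith("_kernel") else v)
        for k, v in d.get("meta", {}).items()
    }
    return GroundTruth(
        b0=d["b0"], phi=np.array(d["phi"]), filter_k=np.array(d["filter_k"]),
        rho=np.array(d["rho"]), meta=meta,
    )


def write_params_json(params: ModelParams, path: str | Path) -> None:
    payload = {
        "b0": params.b0,
        "phi": params.phi.tolist(),
        "k": params.k.tolist(),
        "rho": params.rho.tolist(),
        "level": params.level,
        "free": list(params.free),
        "hyper": {k: _kernel_to_dict(v) for k, v in params.hyper.items()},
    }
    Path(path).write_text(json.dumps(payload), encoding="utf-8")


def read_params_json(path: str | Path) -> ModelParams:
    d = json.loads(Path(path).read_text(encoding="utf-8"))
    return ModelParams(
        b0=d["b0"], phi=np.array(d["phi"]), k=np.array(d["k"]), rho=np.array(d["rho"]),
        level=d["level"], free=tuple(d["free"]),
        hyper={k: _kernel_from_dict(v) for k, v in d["hyper"].items()},
    )


def write_partition_json(result: PartitionResult, path: str | Path, provenance: dict | None = None) -> None:
    payload = result.as_dict()
    if provenance:
        payload["provenance"] = provenance
    Path(path).write_text(json.dumps(payload), encoding="utf-8")


# ---------------------------------------------------------------------------
# configuration


@dataclass
class PipelineConfig:
    """Validated configuration for an end-to-end run."""

    delta_t: float = 0.04
    dead_time: float = 0.01
    m: int = 25
    matern_nu: float = 1.5
    n_folds: int = 10
    seed: int = 0
    rate_cap: float = 50.0
    standardize: bool = True
    history: str = "pad"
    grids: dict[str, GridSpec] | None = None
    simulate: dict[str, Any] = field(default_factory=dict)
    spikes_file: str | None = None
    stimulus_file: str | None = None

    def __post_init__(self) -> None:
        if not self.delta_t > 0:
            raise ValueError("delta_t must be positive")
        if not 0 <= self.dead_time < self.delta_t:
            raise ValueError("dead_time must lie in [0, delta_t)")
        if self.m < 1 or self.n_folds < 1:
            raise ValueError("m and n_folds must be positive counts")
        if self.history not in ("pad", "drop"):
            raise ValueError("history must be 'pad' or 'drop'")

    def config_hash(self) -> str:
        blob = json.dumps(
            {
                k: (repr(v) if k == "grids" else v)
                for k, v in dataclasses.asdict(self).items()
            },
            sort_keys=True, default=str,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def provenance(self) -> dict:
        return {"config_hash": self.config_hash(), "seed": self.seed, "version": __version__}


def _grids_from_config(d: dict) -> dict[str, GridSpec]:
    grids = {}
    for level, g in d.items():
        grids[level] = GridSpec(
            family=g["family"],
            scales=tuple(g["scales"]),
            lengths=tuple(g.get("lengths", ())),
            corrs=tuple(g.get("corrs", ())),
            nu=g.get("nu", 1.5),
        )
    return grids


def load_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    """Load a YAML config file, applying keyword overrides."""
    raw: dict[str, Any] = {}
    if path is not None:
        p = Path(path)
        if not p.exists():
            raise FileNotFoundError(f"config file not found: {p}")
        raw = yaml.safe_load(p.read_text(encoding="utf-8")) or {}
    raw.update(overrides)
    if isinstance(raw.get("grids"), dict) and raw["grids"]:
        first = next(iter(raw["grids"].values()))
        if isinstance(first, dict):
            raw["grids"] = _grids_from_config(raw["grids"])
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**raw)


# ---------------------------------------------------------------------------
# end-to-end pipeline


def run_pipeline(
    config: PipelineConfig,
    out_dir: str | Path | None = None,
    n_cells: int | None = None,
) -> tuple[list[PartitionResult], list[PartitionResult], GroupSummary]:
    """Simulate (or load) cells, fit the hierarchy, partition, aggregate.

    Returns (cv partitions, train partitions, cv group summary). Per-cell
    failures are logged and the cell skipped. When ``out_dir`` is given,
    per-cell partition JSON and the group summary CSV are written there
    with provenance attached.
    """
    from .model import NestedPoissonGLM
    from .synth import draw_ground_truth, generate_stimulus, simulate_raster

    sim = dict(config.simulate)
    for key in ("phi_kernel", "rho_kernel"):
        if isinstance(sim.get(key), dict):
            sim[key] = KernelSpec(**sim[key])
    if n_cells is None:
        n_cells = int(sim.pop("n_cells", 1))
    else:
        sim.pop("n_cells", None)
    cell_types = sim.pop("cell_types", None)

    cells = []
    if config.spikes_file and config.stimulus_file:
        stimulus = read_stimulus_csv(config.stimulus_file)
        spikes = read_spike_times_csv(config.spikes_file, stimulus.n_trials)
        from .preprocess import bin_spikes

        pulse_times = [stimulus.pulse_times()] * stimulus.n_trials
        raster = bin_spikes(
            spikes, pulse_times, config.delta_t, config.dead_time,
            is_frozen=stimulus.is_frozen,
        )
        cells.append(("cell0", None, raster, stimulus))
    else:
        n_trials = int(sim.pop("n_trials", 36))
        n_pulses = int(sim.pop("n_pulses", 2500))
        mean_mV = float(sim.pop("mean_mV", -800.0))
        sd_mV = float(sim.pop("sd_mV", 280.0))
        frozen_fraction = float(sim.pop("frozen_fraction", 0.5))
        for c in range(n_cells):
            cell_seed = config.seed + 1000 * c
            stimulus = generate_stimulus(
                n_trials, n_pulses, mean_mV, sd_mV, frozen_fraction, seed=cell_seed
            )
            truth = draw_ground_truth(
                K=n_trials, T=n_pulses, m=config.m, seed=cell_seed, **sim
            )
            raster = simulate_raster(
                truth, stimulus, delta_t=config.delta_t, seed=cell_seed,
                rate_cap=config.rate_cap,
            )
            ctype = cell_types[c % len(cell_types)] if cell_types else None
            cells.append((f"cell{c}", ctype, raster, stimulus))

    results_cv: list[PartitionResult] = []
    results_train: list[PartitionResult] = []
    failures = 0
    for cell_id, ctype, raster, stimulus in cells:
        try:
            glm = NestedPoissonGLM(
                raster, stimulus, m=config.m, standardize=config.standardize,
                history=config.history, matern_nu=config.matern_nu,
                cell_id=cell_id, cell_type=ctype,
            )
            res = glm.fit(grids=config.grids, n_folds=config.n_folds, seed=config.seed)
        except Exception:
            logger.exception("cell %s failed; skipping", cell_id)
            failures += 1
            continue
        results_cv.append(res.partition_cv)
        results_train.append(res.partition_train)
        if out_dir is not None:
            out = Path(out_dir)
            out.mkdir(parents=True, exist_ok=True)
            write_partition_json(
                res.partition_cv, out / f"{cell_id}_partition_cv.json", config.provenance()
            )
            write_partition_json(
                res.partition_train, out / f"{cell_id}_partition_train.json", config.provenance()
            )

    if not results_cv:
        raise RuntimeError("all cells failed")
    summary = group_summary(results_cv)
    if out_dir is not None:
        summary.table.to_csv(Path(out_dir) / "group_summary_cv.csv")
        group_summary(results_train).table.to_csv(Path(out_dir) / "group_summary_train.csv")
    if failures:
        logger.warning("%d cell(s) failed during the pipeline", failures)
    return results_cv, results_train, summary
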