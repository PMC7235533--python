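"""Variance partitioning by log-likelihood gain against the saturated bound.

With L_BS <= L_NS <= L_LNP <= L_PSTH <= L_sat evaluated on the same data,
the explainable gain L_sat - L_BS is split into

    P_nonstat = (L_NS - L_BS)   / (L_sat - L_BS)   trial-to-trial drift
    P_lin     = (L_LNP - L_NS)  / (L_sat - L_BS)   linear stimulus drive
    P_nonlin  = (L_PSTH - L_LNP)/ (L_sat - L_BS)   residual stimulus-locked
    P_sig     = (L_PSTH - L_BS) / (L_sat - L_BS)   all of the above
    P_noise   = 1 - P_sig                          unexplained

evaluated either on the training data (how much structure is present) or
on held-out folds (how much generalizes). The collapse rule upstream makes
the L's monotone, so all fractions land in [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .data import SpikeRaster
from .design import StimulusDesign
from .glm import (
    ModelParams,
    fit_baseline,
    fit_map_block,
    poisson_loglik,
    saturated_loglik,
)
from .selection import SelectionResult, _subraster

__all__ = [
    "PartitionResult",
    "GroupSummary",
    "compute_partition",
    "evaluate_hierarchy",
    "group_summary",
    "CELL_TYPES",
]

logger = logging.getLogger(__name__)

CELL_TYPES = ("ON", "OFF", "ON-OFF")
_COMPONENTS = ("P_nonstat", "P_lin", "P_nonlin", "P_noise")


@dataclass
class PartitionResult:
    """Log-likelihoods and derived fractions for one cell, one evaluation."""

    L_BS: float
    L_NS: float
    L_LNP: float
    L_PSTH: float
    L_sat: float
    P_sig: float
    P_noise: float
    P_nonstat: float
    P_lin: float
    P_nonlin: float
    evaluation: str = "cv"
    cell_id: str | None = None
    cell_type: str | None = None

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@dataclass
class GroupSummary:
    """Mean and dispersion of each partition component by cell type."""

    table: pd.DataFrame
    dispersion: str = "sd"


def compute_partition(
    L_BS: float,
    L_NS: float,
    L_LNP: float,
    L_PSTH: float,
    L_sat: float,
    evaluation: str = "cv",
    clamp_tol: float = 1e-9,
    **meta,
) -> PartitionResult:
    """Turn five monotone log-likelihoods into the gain fractions.

    Inputs must already honour the collapse rule (monotone L's); a tiny
    negative gain from numerical tolerance is clamped to 0 with a log
    entry, anything larger is an error.
    """
    denom = L_sat - L_BS
    if denom <= 0:
        raise ValueError(
            "undefined partition: saturated and baseline log-likelihood coincide "
            f"(L_sat={L_sat}, L_BS={L_BS})"
        )
    gains = np.array([L_NS - L_BS, L_LNP - L_NS, L_PSTH - L_LNP, L_sat - L_PSTH]) / denom
    if (gains < -clamp_tol).any():
        raise ValueError(f"log-likelihoods are not monotone: gains {gains}")
    if (gains < 0).any():
        logger.info("clamped tiny negative gains %s to 0", gains[gains < 0])
        gains = np.clip(gains, 0.0, None)
        gains = gains / gains.sum()  # keep the partition closed
    p_nonstat, p_lin, p_nonlin, p_noise = (float(g) for g in gains)
    return PartitionResult(
        L_BS=L_BS,
        L_NS=L_NS,
        L_LNP=L_LNP,
        L_PSTH=L_PSTH,
        L_sat=L_sat,
        P_sig=p_nonstat + p_lin + p_nonlin,
        P_noise=p_noise,
        P_nonstat=p_nonstat,
        P_lin=p_lin,
        P_nonlin=p_nonlin,
        evaluation=evaluation,
        **meta,
    )


def _train_refit(
    selection: SelectionResult, raster: SpikeRaster, design: StimulusDesign | None
) -> dict[str, ModelParams]:
    """Refit each level on the full repeating-trial raster at the selected
    hyper-parameters, honouring collapse flags."""
    mask = design.bin_mask if design is not None else None
    params: dict[str, ModelParams] = {}
    current = fit_baseline(raster, design, bin_mask=mask)
    params["BS"] = current
    for level, block in (("NS", "phi"), ("NS-LNP", "k"), ("NS-PSTH", "rho")):
        hyper = selection.best_hyper[level]
        if selection.collapsed[level] or hyper is None:
            current = replace(current, level=level)
        else:
            current = fit_map_block(
                raster, design, current, block, hyper,
                bin_mask=mask, trial_index=raster.trial_ids,
            )
        params[level] = current
    return params


def evaluate_hierarchy(
    selection: SelectionResult,
    raster: SpikeRaster,
    design: StimulusDesign | None,
    evaluation: str = "cv",
    **meta,
) -> PartitionResult:
    """Compute the partition for one cell in train or cv mode.

    ``train``: every level is refit on the full repeating-trial raster at
    its selected hyper-parameters and scored on that same data; the
    saturated bound uses the same data. ``cv``: the per-fold held-out
    log-likelihoods from the selection stage are averaged, and the
    saturated bound is computed per fold from the held-out counts
    themselves, then averaged — numerator and denominator stay on the same
    data.
    """
    mask = design.bin_mask if design is not None else None
    if evaluation == "train":
        params = _train_refit(selection, raster, design)
        L = {lv: poisson_loglik(p, raster, design, bin_mask=mask) for lv, p in params.items()}
        L_sat = saturated_loglik(raster, bin_mask=mask)
    elif evaluation == "cv":
        L = {lv: float(v.mean()) for lv, v in selection.per_fold_cvll.items()}
        sat = [
            saturated_loglik(_subraster(raster, st.test), bin_mask=mask)
            for st in selection.fold_states
        ]
        L_sat = float(np.mean(sat))
    else:
        raise ValueError("evaluation must be 'train' or 'cv'")
    return compute_partition(
        L["BS"], L["NS"], L["NS-LNP"], L["NS-PSTH"], L_sat, evaluation=evaluation, **meta
    )


def group_summary(
    results: list[PartitionResult],
    cell_types: list[str] | None = None,
    dispersion: str = "sd",
) -> GroupSummary:
    """Aggregate per-cell fractions into a per-type summary table.

    Rows: All plus each cell type present; columns: the four components
    (NS drift, linear, non-linear, unexplained), each as ``mean`` and
    ``sd``/``sem`` across member cells.
    """
    if not results:
        raise ValueError("no partition results to summarize")
    if dispersion not in ("sd", "sem"):
        raise ValueError("dispersion must be 'sd' or 'sem'")
    if cell_types is None:
        cell_types = [r.cell_type or "unknown" for r in results]
    if len(cell_types) != len(results):
        raise ValueError("one cell type label per result required")
    bad = sorted({t for t in cell_types if t not in CELL_TYPES and t != "unknown"})
    if bad:
        raise ValueError(f"unknown cell type labels {bad}; allowed: {list(CELL_TYPES)}")

    df = pd.DataFrame([r.as_dict() for r in results])
    df["cell_type"] = cell_types
    rows = []
    groups = [("All", df)] + [
        (t, df[df["cell_type"] == t]) for t in CELL_TYPES if (df["cell_type"] == t).any()
    ]
    for name, g in groups:
        row: dict[str, float | str | int] = {"group": name, "n_cells": len(g)}
        for comp in _COMPONENTS:
            vals = g[comp].to_numpy(dtype=float)
            row[f"{comp}_mean"] = float(vals.mean())
            sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
            row[f"{comp}_sd"] = sd
            row[f"{comp}_sem"] = sd / np.sqrt(len(vals)) if len(vals) > 0 else 0.0
        rows.append(row)
    return GroupSummary(table=pd.DataFrame(rows).set_index("group"), dispersion=dispersion)
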