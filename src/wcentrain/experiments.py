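"""Orchestration of the computational experiments.

* (f_in, Lambda) heat maps of the entrainment index per divisiveness q,
* convergence-time maps restricted to the region fully entrained at every q,
* sweeps over the initial phase difference delta_phi,
* the paired q = 0 vs q = 1 generalization study over a collection of valid
  parameter sets, each probed with its nine-setting input battery.

All sweeps are deterministic given the solver configuration; per-cell
failures are recorded as missing values and never abort a sweep.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .drive import DriveProtocol, run_protocol
from .errors import WcentrainError
from .metrics import (FULL_ENTRAINMENT_THRESHOLD, OSCILLATION_THRESHOLD,
                      evaluate_entrainment, peak_to_peak)
from .model import MicrocircuitParams, SolverConfig, DEFAULT_SOLVER
from .search import CandidateSet, make_input_settings

__all__ = [
    "SweepResult",
    "PairedStudyResult",
    "default_f_in_grid",
    "default_lambda_grid",
    "entrainment_sweep",
    "convergence_sweep",
    "phase_sweep",
    "generalization_study",
]

logger = logging.getLogger(__name__)

CANONICAL_DELTA_PHI = (0.0, math.pi / 2, math.pi, 3 * math.pi / 2)


def default_f_in_grid() -> np.ndarray:
    """Drive-frequency grid spanning the delta-to-low-alpha regimes."""
    return np.arange(1.0, 14.0 + 1e-9, 0.25)


def default_lambda_grid() -> np.ndarray:
    """Drive-amplitude grid from weak to strong forcing."""
    return np.arange(0.05, 0.70 + 1e-9, 0.05)


@dataclass
class SweepResult:
    """Entrainment indices and convergence times on an (f_in, Lambda) grid.

    ``index[i, j]`` corresponds to ``f_in_grid[i]`` and ``lambda_grid[j]``;
    convergence times are NaN wherever the index does not exceed the
    complete-entrainment threshold (or the run failed).
    """

    f_in_grid: np.ndarray
    lambda_grid: np.ndarray
    q: float
    delta_phi: float
    index: np.ndarray
    convergence: np.ndarray

    def __post_init__(self):
        expected = (len(self.f_in_grid), len(self.lambda_grid))
        if self.index.shape != expected or self.convergence.shape != expected:
            raise ValueError("matrix shapes must match the grid axes")

    def to_frame(self) -> pd.DataFrame:
        """Long-format view: one row per grid cell."""
        rows = []
        for i, f in enumerate(self.f_in_grid):
            for j, lam in enumerate(self.lambda_grid):
                rows.append({"f_in": f, "Lambda": lam, "q": self.q,
                             "delta_phi": self.delta_phi,
                             "index": self.index[i, j],
                             "convergence_time": self.convergence[i, j]})
        return pd.DataFrame(rows)


def _sweep_cell(params: MicrocircuitParams, f_in: float, lam: float,
                delta_phi: float, solver: SolverConfig, settle: float,
                total: float) -> Tuple[float, float]:
    drive = DriveProtocol(Lambda=lam, f_in=f_in, delta_phi=delta_phi,
                          settle=settle, total=total)
    try:
        traj, realized = run_protocol(params, drive, solver=solver)
        res = evaluate_entrainment(traj, realized.t_switch, f_in,
                                   realized.phi0)
    except WcentrainError as exc:
        logger.debug("cell (f_in=%.3f, Lambda=%.3f) failed: %s",
                     f_in, lam, exc)
        return np.nan, np.nan
    conv = res.convergence_time
    return res.index, np.nan if conv is None else conv


def entrainment_sweep(params: MicrocircuitParams, q: float,
                      f_in_grid: Optional[Sequence[float]] = None,
                      lambda_grid: Optional[Sequence[float]] = None,
                      delta_phi: float = 0.0,
                      solver: SolverConfig = DEFAULT_SOLVER,
                      settle: float = 10.0, total: float = 20.0,
                      workers: int = 1) -> SweepResult:
    """One simulate-and-measure run per (f_in, Lambda) grid cell at fixed q.

    Cells are independent, so results are identical for any worker count.
    """
    f_grid = np.asarray(default_f_in_grid() if f_in_grid is None
                        else f_in_grid, dtype=float)
    l_grid = np.asarray(default_lambda_grid() if lambda_grid is None
                        else lambda_grid, dtype=float)
    params = params.with_q(q)
    cells = [(i, j) for i in range(f_grid.size) for j in range(l_grid.size)]
    if workers > 1:
        from joblib import Parallel, delayed

        outputs = Parallel(n_jobs=workers)(
            delayed(_sweep_cell)(params, f_grid[i], l_grid[j], delta_phi,
                                 solver, settle, total) for i, j in cells)
    else:
        outputs = [_sweep_cell(params, f_grid[i], l_grid[j], delta_phi,
                               solver, settle, total) for i, j in cells]
    index = np.full((f_grid.size, l_grid.size), np.nan)
    conv = np.full((f_grid.size, l_grid.size), np.nan)
    for (i, j), (idx_val, conv_val) in zip(cells, outputs):
        index[i, j] = idx_val
        conv[i, j] = conv_val
    return SweepResult(f_in_grid=f_grid, lambda_grid=l_grid, q=q,
                       delta_phi=delta_phi, index=index, convergence=conv)


def common_entrained_mask(sweeps: Sequence[SweepResult],
                          threshold: float = FULL_ENTRAINMENT_THRESHOLD,
                          ) -> np.ndarray:
    """Cells fully entrained (index > threshold) in every sweep."""
    mask = np.ones_like(sweeps[0].index, dtype=bool)
    for sw in sweeps:
        mask &= np.nan_to_num(sw.index, nan=0.0) > threshold
    return mask


def convergence_sweep(params: MicrocircuitParams, q_values: Sequence[float],
                      f_in_grid: Optional[Sequence[float]] = None,
                      lambda_grid: Optional[Sequence[float]] = None,
                      delta_phi: float = 0.0,
                      solver: SolverConfig = DEFAULT_SOLVER,
                      ) -> Dict[float, SweepResult]:
    """Convergence times on the region fully entrained at *all* q values.

    Cells outside the common region have their convergence time masked to
    NaN.  An empty common region is reported with a warning, not an error.
    """
    sweeps = {q: entrainment_sweep(params, q, f_in_grid, lambda_grid,
                                   delta_phi, solver)
              for q in q_values}
    mask = common_entrained_mask(list(sweeps.values()))
    if not mask.any():
        logger.warning("no grid cell is fully entrained at every q")
    for sw in sweeps.values():
        sw.convergence = np.where(mask, sw.convergence, np.nan)
    return sweeps


def phase_sweep(params: MicrocircuitParams, q_values: Sequence[float],
                delta_phis: Sequence[float] = CANONICAL_DELTA_PHI,
                f_in_grid: Optional[Sequence[float]] = None,
                lambda_grid: Optional[Sequence[float]] = None,
                solver: SolverConfig = DEFAULT_SOLVER,
                ) -> pd.DataFrame:
    """Median convergence time per (q, delta_phi).

    For each delta_phi the convergence statistics are taken over the region
    fully entrained at every q (as in the convergence maps).  Returns a
    tidy frame with columns q, delta_phi, median_convergence, n_cells.
    """
    rows = []
    for dphi in delta_phis:
        sweeps = convergence_sweep(params, q_values, f_in_grid, lambda_grid,
                                   dphi, solver)
        for q, sw in sweeps.items():
            vals = sw.convergence[np.isfinite(sw.convergence)]
            rows.append({"q": q, "delta_phi": dphi,
                         "median_convergence":
                             float(np.median(vals)) if vals.size else np.nan,
                         "n_cells": int(vals.size)})
    return pd.DataFrame(rows)


@dataclass
class PairedStudyResult:
    """Outcome of the paired q = 0 vs q = 1 generalization study.

    ``runs`` holds one row per (set, input setting, q); ``pairs`` one row
    per (set, setting) with both q values side by side.  Convergence-time
    pairing is restricted to combinations fully entrained at both q.
    """

    runs: pd.DataFrame
    pairs: pd.DataFrame
    n_sets_used: int
    n_sets_excluded: int
    summary: Dict[str, float] = field(default_factory=dict)

    def compute_summary(self) -> Dict[str, float]:
        p = self.pairs
        both = p[(p["index_q0"] > FULL_ENTRAINMENT_THRESHOLD)
                 & (p["index_q1"] > FULL_ENTRAINMENT_THRESHOLD)]
        conv_ok = both.dropna(subset=["conv_q0", "conv_q1"])
        s = {
            "n_pairs": float(len(p)),
            "median_index_q0": float(p["index_q0"].median()),
            "median_index_q1": float(p["index_q1"].median()),
            "iqr_low_index_q0": float(p["index_q0"].quantile(0.25)),
            "iqr_high_index_q0": float(p["index_q0"].quantile(0.75)),
            "iqr_low_index_q1": float(p["index_q1"].quantile(0.25)),
            "iqr_high_index_q1": float(p["index_q1"].quantile(0.75)),
            "median_paired_index_diff":
                float((p["index_q1"] - p["index_q0"]).median()),
            "n_pairs_fully_entrained_both": float(len(both)),
            "median_conv_q0": float(conv_ok["conv_q0"].median())
                if len(conv_ok) else math.nan,
            "median_conv_q1": float(conv_ok["conv_q1"].median())
                if len(conv_ok) else math.nan,
            "median_paired_conv_diff":
                float((conv_ok["conv_q1"] - conv_ok["conv_q0"]).median())
                if len(conv_ok) else math.nan,
        }
        self.summary = s
        return s


def _study_one(candidate: CandidateSet, setting, q: float, delta_phi: float,
               solver: SolverConfig, settle: float, total: float):
    params = candidate.params(q)
    drive = DriveProtocol(Lambda=setting.Lambda, f_in=setting.f_in,
                          delta_phi=delta_phi, settle=settle, total=total)
    traj, realized = run_protocol(params, drive, solver=solver)
    # post-onset oscillation check (sets failing it are excluded entirely)
    tail_pp = peak_to_peak(traj, "E", (total - 3.0, total))
    if tail_pp <= OSCILLATION_THRESHOLD:
        raise WcentrainError("no post-onset oscillation")
    res = evaluate_entrainment(traj, realized.t_switch, setting.f_in,
                               realized.phi0)
    return res


def generalization_study(collection: Sequence[CandidateSet],
                         delta_phi: float = 3 * math.pi / 2,
                         solver: SolverConfig = DEFAULT_SOLVER,
                         settle: float = 10.0, total: float = 20.0,
                         ) -> PairedStudyResult:
    """Paired q = 0 vs q = 1 comparison over a collection of valid sets.

    Each set is probed with its nine input settings at both q extremes.  A
    set that fails to oscillate after drive onset under any setting (at
    either q) is excluded from the pairing.  delta_phi defaults to 3 pi / 2,
    the phase that promotes the fastest convergence at every q, so neither
    extreme is favored.
    """
    run_rows: List[dict] = []
    pair_rows: List[dict] = []
    n_used = 0
    n_excluded = 0
    for set_id, cand in enumerate(collection):
        settings = make_input_settings(cand)
        results: Dict[Tuple[int, float], object] = {}
        excluded = False
        for s_id, setting in enumerate(settings):
            for q in (0.0, 1.0):
                try:
                    res = _study_one(cand, setting, q, delta_phi, solver,
                                     settle, total)
                except WcentrainError as exc:
                    logger.info("set %d excluded (setting %d, q=%g): %s",
                                set_id, s_id, q, exc)
                    excluded = True
                    break
                results[(s_id, q)] = res
            if excluded:
                break
        if excluded:
            n_excluded += 1
            continue
        n_used += 1
        for s_id, setting in enumerate(settings):
            r0 = results[(s_id, 0.0)]
            r1 = results[(s_id, 1.0)]
            for q, r in ((0.0, r0), (1.0, r1)):
                run_rows.append({"set_id": set_id, "setting_id": s_id,
                                 "Lambda": setting.Lambda,
                                 "f_in": setting.f_in, "q": q,
                                 "index": r.index,
                                 "convergence_time": r.convergence_time})
            pair_rows.append({
                "set_id": set_id, "setting_id": s_id,
                "Lambda": setting.Lambda, "f_in": setting.f_in,
                "index_q0": r0.index, "index_q1": r1.index,
                "conv_q0": r0.convergence_time,
                "conv_q1": r1.convergence_time,
            })
    result = PairedStudyResult(runs=pd.DataFrame(run_rows),
                               pairs=pd.DataFrame(pair_rows),
                               n_sets_used=n_used,
                               n_sets_excluded=n_excluded)
    if len(result.pairs):
        result.compute_summary()
    return result
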