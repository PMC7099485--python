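"""Sampling, screening and optimization of the parameter space.

A parameter set is *valid* for the divisiveness comparison when

1. it follows the mouse-V1 connectivity ratios (w7 = w3, w2 = 0.54 w3,
   w6 = 0.33 w3) — true by construction here;
2. it produces sustained oscillations under constant drive at both q = 0
   and q = 1;
3. the peak-to-peak amplitudes of E(t) at q = 0 and q = 1 differ by less
   than 0.001, so the two extremes are directly comparable;
4. the peak-to-peak amplitude of I_soma(t) is at least that of E(t) at both
   q values, which rules out degenerate circuits whose soma-targeting
   population is effectively silent (reducing the model to a classic
   two-population system).

Candidates are drawn uniformly from the hypercube P in [0, 5],
w_k in [0, 35] (k in {1, 3, 4, 5}); those passing condition 2 seed a staged
derivative-free minimization of the amplitude mismatch |ppE(q=0) - ppE(q=1)|
subject to condition 4 and the hypercube (see `OptimizeConfig`).  Surviving
sets are deduplicated at a relative tolerance of 0.05.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import List, NamedTuple, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import brentq, minimize

from .errors import IntegrationError, ModelDomainError, NoOscillationError
from .metrics import (OSCILLATION_THRESHOLD, STEADY_WINDOW, natural_frequency,
                      peak_to_peak)
from .model import MicrocircuitParams, SolverConfig, simulate

__all__ = [
    "ParameterBounds",
    "CandidateSet",
    "InputSetting",
    "OptimizeConfig",
    "PipelineResult",
    "derive_dependent_weights",
    "sample_candidates",
    "check_conditions",
    "optimize_amplitude_match",
    "dedupe",
    "make_input_settings",
    "collect_valid_sets",
]

logger = logging.getLogger(__name__)

#: Horizon of the screening simulations (s); diagnostics use the final 3 s.
SCREEN_HORIZON = 10.0

#: Millisecond-step RK4 is ample for screening amplitudes (agreement with
#: the reference step is ~1e-7) and integrates ~4x faster.
SCREEN_SOLVER = SolverConfig(substeps=1)

#: Condition-3 threshold on |ppE(q=0) - ppE(q=1)| (absolute units).
AMPLITUDE_MATCH_TOL = 1e-3

#: Deduplication tolerance (relative, scaled by the largest coordinate).
DEDUPE_TOL = 0.05

PENALTY_WEIGHT = 1e3


@dataclass(frozen=True)
class ParameterBounds:
    """Sampling hypercube for the five free parameters."""

    P: Tuple[float, float] = (0.0, 5.0)
    w: Tuple[float, float] = (0.0, 35.0)

    def as_array(self) -> np.ndarray:
        return np.array([self.P, self.w, self.w, self.w, self.w])


class InputSetting(NamedTuple):
    """One (amplitude, frequency) drive setting."""

    Lambda: float
    f_in: float


@dataclass(frozen=True)
class CandidateSet:
    """A free-parameter draw with its screening diagnostics.

    Diagnostics (intrinsic frequency and steady-state peak-to-peak
    amplitudes of the three populations) are recorded separately for q = 0
    and q = 1; frequency fields are present only when the corresponding
    oscillation exists.  ``c1`` is true by construction (ratio rule).
    """

    P: float
    w1: float
    w3: float
    w4: float
    w5: float
    seed: Optional[int] = None
    draw_index: Optional[int] = None
    optimizer_iterations: int = 0
    f_q0: Optional[float] = None
    f_q1: Optional[float] = None
    ppE_q0: Optional[float] = None
    ppE_q1: Optional[float] = None
    ppId_q0: Optional[float] = None
    ppId_q1: Optional[float] = None
    ppIs_q0: Optional[float] = None
    ppIs_q1: Optional[float] = None
    c1: bool = True
    c2: Optional[bool] = None
    c3: Optional[bool] = None
    c4: Optional[bool] = None
    error: Optional[str] = None

    def free_vector(self) -> np.ndarray:
        return np.array([self.P, self.w1, self.w3, self.w4, self.w5])

    def params(self, q: float, tau: float = 0.05) -> MicrocircuitParams:
        return MicrocircuitParams.from_free_weights(
            P=self.P, w1=self.w1, w3=self.w3, w4=self.w4, w5=self.w5, q=q,
            tau=tau)

    @property
    def all_conditions(self) -> bool:
        return bool(self.c1 and self.c2 and self.c3 and self.c4)


def derive_dependent_weights(w3: float) -> Tuple[float, float, float]:
    """Dependent weights (w2, w6, w7) = (0.54 w3, 0.33 w3, w3)."""
    if w3 < 0:
        raise ModelDomainError("w3 must be non-negative")
    return 0.54 * w3, 0.33 * w3, w3


def sample_candidates(n: int, seed: int,
                      bounds: ParameterBounds = ParameterBounds(),
                      ) -> List[CandidateSet]:
    """``n`` independent uniform draws of (P, w1, w3, w4, w5)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    arr = bounds.as_array()
    draws = rng.uniform(arr[:, 0], arr[:, 1], size=(n, 5))
    return [CandidateSet(P=v[0], w1=v[1], w3=v[2], w4=v[3], w5=v[4],
                         seed=seed, draw_index=i)
            for i, v in enumerate(draws)]


def _diagnose(params: MicrocircuitParams, solver: SolverConfig,
              horizon: float) -> dict:
    """Steady-state amplitudes and (if oscillatory) intrinsic frequency."""
    traj = simulate(params, horizon, solver=solver)
    win = (horizon - STEADY_WINDOW, horizon)
    out = {
        "ppE": peak_to_peak(traj, "E", win),
        "ppId": peak_to_peak(traj, "I_dend", win),
        "ppIs": peak_to_peak(traj, "I_soma", win),
        "f": None,
    }
    if out["ppE"] > OSCILLATION_THRESHOLD:
        try:
            out["f"] = natural_frequency(traj)
        except NoOscillationError:
            out["f"] = None
    return out


def check_conditions(candidate: CandidateSet,
                     solver: Optional[SolverConfig] = None,
                     horizon: float = SCREEN_HORIZON) -> CandidateSet:
    """Screen a candidate against conditions 2-4.

    Condition 2 (sustained oscillation at both q) requires the steady-state
    peak-to-peak amplitude of E to exceed the oscillation threshold *and* a
    consistently measurable dominant frequency.  Integration failures mark
    the candidate invalid rather than raising.
    """
    if solver is None:
        solver = SCREEN_SOLVER
    try:
        d0 = _diagnose(candidate.params(0.0), solver, horizon)
        osc0 = d0["ppE"] > OSCILLATION_THRESHOLD and d0["f"] is not None
        if not osc0:
            return replace(candidate, c2=False, f_q0=d0["f"],
                           ppE_q0=d0["ppE"], ppId_q0=d0["ppId"],
                           ppIs_q0=d0["ppIs"])
        d1 = _diagnose(candidate.params(1.0), solver, horizon)
        osc1 = d1["ppE"] > OSCILLATION_THRESHOLD and d1["f"] is not None
    except IntegrationError as exc:
        return replace(candidate, c2=False, error=str(exc))
    c2 = osc0 and osc1
    c3 = c2 and abs(d0["ppE"] - d1["ppE"]) < AMPLITUDE_MATCH_TOL
    c4 = c2 and d0["ppIs"] >= d0["ppE"] and d1["ppIs"] >= d1["ppE"]
    return replace(candidate, c2=c2, c3=c3, c4=c4,
                   f_q0=d0["f"], f_q1=d1["f"],
                   ppE_q0=d0["ppE"], ppE_q1=d1["ppE"],
                   ppId_q0=d0["ppId"], ppId_q1=d1["ppId"],
                   ppIs_q0=d0["ppIs"], ppIs_q1=d1["ppIs"])


@dataclass(frozen=True)
class OptimizeConfig:
    """Settings for the amplitude-matching optimization.

    The problem is solved in stages: a coarse grid pre-search over the
    weights that control the soma-targeting population's amplitude (w3
    through its self-inhibition, w4, and its drive w5), a simplex
    feasibility phase that minimizes the condition-4 violation, a simplex
    matching phase that minimizes the amplitude mismatch under an exact
    (L1) condition-4 penalty, and a final root-polish of the *signed*
    mismatch along one coordinate.  ``margin`` keeps the feasibility target
    strictly inside the condition-4 region so the simplex does not stall on
    the constraint boundary.
    """

    maxfev: int = 500
    xatol: float = 1e-3
    fatol: float = 1e-9
    penalty: float = PENALTY_WEIGHT
    match_penalty: float = 100.0
    margin: float = 0.002
    feasibility_reject: float = 0.05
    polish_tol: float = AMPLITUDE_MATCH_TOL
    solver: SolverConfig = field(
        default_factory=lambda: SolverConfig(substeps=1))
    horizon: float = SCREEN_HORIZON


@dataclass(frozen=True)
class OptimizationOutcome:
    candidate: Optional[CandidateSet]
    accepted: bool
    reason: str
    iterations: int


class _AmplitudeProblem:
    """Shared state for the staged amplitude-matching optimization."""

    def __init__(self, bounds_arr: np.ndarray, cfg: OptimizeConfig):
        self.b = bounds_arr
        self.cfg = cfg
        self.nfev = 0

    def _bounds_penalty(self, v: np.ndarray) -> float:
        lo, hi = self.b[:, 0], self.b[:, 1]
        oob = np.sum(np.maximum(0.0, lo - v) ** 2
                     + np.maximum(0.0, v - hi) ** 2)
        return self.cfg.penalty * float(oob)

    def diagnostics(self, v: np.ndarray):
        self.nfev += 1
        vc = np.clip(v, self.b[:, 0], self.b[:, 1])
        cand = CandidateSet(P=vc[0], w1=vc[1], w3=vc[2], w4=vc[3], w5=vc[4])
        d0 = _diagnose(cand.params(0.0), self.cfg.solver, self.cfg.horizon)
        d1 = _diagnose(cand.params(1.0), self.cfg.solver, self.cfg.horizon)
        return d0, d1

    def violation(self, d0: dict, d1: dict) -> float:
        m = self.cfg.margin
        return (max(0.0, d0["ppE"] - d0["ppIs"] + m)
                + max(0.0, d1["ppE"] - d1["ppIs"] + m))

    def feasibility(self, v: np.ndarray) -> float:
        """Condition-4 violation (with margin), guarded against losing the
        oscillation or leaving the hypercube."""
        pen = self._bounds_penalty(v)
        try:
            d0, d1 = self.diagnostics(v)
        except IntegrationError:
            return 10.0 * self.cfg.penalty + pen
        ppE_min = min(d0["ppE"], d1["ppE"])
        if ppE_min <= OSCILLATION_THRESHOLD:
            # losing the oscillation must cost more than any violation can
            return self.cfg.penalty * (
                1.0 + (OSCILLATION_THRESHOLD - ppE_min)) + pen
        return self.violation(d0, d1) + pen

    def matching(self, v: np.ndarray) -> float:
        """Amplitude mismatch plus exact-penalty terms."""
        pen = self._bounds_penalty(v)
        try:
            d0, d1 = self.diagnostics(v)
        except IntegrationError:
            return 10.0 * self.cfg.penalty + pen
        ppE_min = min(d0["ppE"], d1["ppE"])
        if ppE_min <= OSCILLATION_THRESHOLD:
            return self.cfg.penalty * (
                1.0 + (OSCILLATION_THRESHOLD - ppE_min)) + pen
        return (abs(d0["ppE"] - d1["ppE"])
                + self.cfg.match_penalty * self.violation(d0, d1) + pen)

    def signed_mismatch(self, v: np.ndarray) -> Optional[float]:
        """ppE(q=0) - ppE(q=1), or None when the point is unusable."""
        try:
            d0, d1 = self.diagnostics(v)
        except IntegrationError:
            return None
        if min(d0["ppE"], d1["ppE"]) <= OSCILLATION_THRESHOLD:
            return None
        return d0["ppE"] - d1["ppE"]

    def presearch(self, v: np.ndarray) -> np.ndarray:
        """Coarse scan of the (w3, w4, w5) directions that set the
        soma-targeting amplitude, seeding the simplex near feasibility."""
        hi = self.b[2:, 1].min()
        best, best_val = v, self.feasibility(v)
        for w3_scale in (0.25, 0.5, 0.75, 1.0, 1.25):
            for w4_scale in (0.75, 1.0, 1.25):
                for w5 in (v[4], 0.5 * (v[4] + hi), hi):
                    vv = v.copy()
                    vv[2] = min(v[2] * w3_scale, hi)
                    vv[3] = min(v[3] * w4_scale, hi)
                    vv[4] = w5
                    val = self.feasibility(vv)
                    if val < best_val:
                        best, best_val = vv, val
        return best


def _polish(problem: _AmplitudeProblem, v: np.ndarray,
            cfg: OptimizeConfig) -> np.ndarray:
    """Zero the signed amplitude mismatch along one coordinate (P, then w1)
    by bracketing and bisection; returns v unchanged when no bracket."""
    g0 = problem.signed_mismatch(v)
    if g0 is None or abs(g0) < cfg.polish_tol:
        return v
    for coord in (0, 1):
        lo, hi = problem.b[coord]
        for delta in (0.02, 0.05, 0.1, 0.2, 0.4):
            for sign in (1.0, -1.0):
                vv = v.copy()
                vv[coord] = np.clip(v[coord] + sign * delta, lo, hi)
                g1 = problem.signed_mismatch(vv)
                if g1 is None or np.sign(g1) == np.sign(g0):
                    continue

                def mismatch_along(x: float) -> float:
                    w = v.copy()
                    w[coord] = x
                    g = problem.signed_mismatch(w)
                    return g if g is not None else 1.0

                try:
                    root = brentq(mismatch_along,
                                  min(v[coord], vv[coord]),
                                  max(v[coord], vv[coord]), xtol=1e-5)
                except ValueError:
                    continue
                out = v.copy()
                out[coord] = root
                return out
    return v


def optimize_amplitude_match(start: CandidateSet,
                             bounds: ParameterBounds = ParameterBounds(),
                             config: OptimizeConfig = OptimizeConfig(),
                             ) -> OptimizationOutcome:
    """Drive a condition-2 start toward a set valid under all 4 conditions.

    Stages: coarse pre-search, Nelder-Mead feasibility phase (condition 4),
    Nelder-Mead amplitude matching (condition 3) under an exact penalty,
    and a final signed-mismatch root polish.  The result is re-screened and
    accepted only when all four conditions hold; starts whose condition-4
    violation cannot be removed are rejected with a reason, as are those
    that lose the oscillation.
    """
    if start.c2 is False:
        return OptimizationOutcome(None, False,
                                   "start does not oscillate (condition 2)",
                                   0)
    barr = bounds.as_array()
    problem = _AmplitudeProblem(barr, config)
    nm_options = {"maxfev": config.maxfev, "xatol": config.xatol,
                  "fatol": config.fatol, "adaptive": True}
    v = problem.presearch(start.free_vector())
    res = minimize(problem.feasibility, v, method="Nelder-Mead",
                   options=nm_options)
    if res.fun > config.feasibility_reject:
        return OptimizationOutcome(
            None, False, "condition-4 feasibility not reachable "
            f"(residual violation {res.fun:.4f})", problem.nfev)
    res = minimize(problem.matching, res.x, method="Nelder-Mead",
                   options=nm_options)
    if not res.success:
        res = minimize(problem.matching, res.x, method="Nelder-Mead",
                       options=nm_options)
    v = np.clip(res.x, barr[:, 0], barr[:, 1])
    v = _polish(problem, v, config)
    cand = CandidateSet(P=v[0], w1=v[1], w3=v[2], w4=v[3], w5=v[4],
                        seed=start.seed, draw_index=start.draw_index,
                        optimizer_iterations=problem.nfev)
    cand = check_conditions(cand, solver=config.solver,
                            horizon=config.horizon)
    if not cand.c2:
        return OptimizationOutcome(None, False,
                                   "oscillation lost during optimization",
                                   problem.nfev)
    if not cand.all_conditions:
        failed = [name for name, ok in
                  (("c3", cand.c3), ("c4", cand.c4)) if not ok]
        return OptimizationOutcome(cand, False,
                                   f"conditions not met: {','.join(failed)}",
                                   problem.nfev)
    return OptimizationOutcome(cand, True, "converged", problem.nfev)


def dedupe(sets: Sequence[CandidateSet],
           tol: float = DEDUPE_TOL) -> List[CandidateSet]:
    """Greedy tolerance-deduplication of parameter vectors, in input order.

    A set is kept iff its (P, w1, w3, w4, w5) vector differs from every
    previously kept vector by more than ``tol`` in the Chebyshev metric,
    scaled by the largest coordinate magnitude in the collection.
    """
    if not sets:
        return []
    vectors = np.array([s.free_vector() for s in sets])
    scale = float(np.max(np.abs(vectors))) or 1.0
    kept_idx: List[int] = []
    for i, v in enumerate(vectors):
        if not kept_idx or np.min(
                np.max(np.abs(vectors[kept_idx] - v), axis=1)) > tol * scale:
            kept_idx.append(i)
    return [sets[i] for i in kept_idx]


def make_input_settings(candidate: CandidateSet) -> Tuple[InputSetting, ...]:
    """The nine-setting battery: Lambda in {0.1P, 0.3P, 0.5P} crossed with
    f_in in {f*(q=0), midpoint, f*(q=1)}."""
    if candidate.f_q0 is None or candidate.f_q1 is None:
        raise ValueError("candidate is missing a measured natural frequency")
    lambdas = (0.1 * candidate.P, 0.3 * candidate.P, 0.5 * candidate.P)
    freqs = (candidate.f_q0, 0.5 * (candidate.f_q0 + candidate.f_q1),
             candidate.f_q1)
    return tuple(InputSetting(Lambda=l, f_in=f)
                 for l in lambdas for f in freqs)


@dataclass
class PipelineResult:
    """Funnel of the sample -> screen -> optimize -> dedupe chain."""

    valid_sets: List[CandidateSet]
    n_sampled: int = 0
    n_oscillatory: int = 0
    n_unique_starts: int = 0
    n_optimized_ok: int = 0
    n_unique_valid: int = 0


def collect_valid_sets(seed: int, target_valid: int = 10,
                       batch_size: int = 2000, max_draws: int = 100_000,
                       bounds: ParameterBounds = ParameterBounds(),
                       screen_solver: SolverConfig = SCREEN_SOLVER,
                       opt_config: OptimizeConfig = OptimizeConfig(),
                       ) -> PipelineResult:
    """Run the full pipeline until ``target_valid`` unique valid sets exist.

    Draws are consumed in batches; each batch is screened, oscillatory
    starts are deduplicated against all previous starts, optimized, and the
    accepted optima deduplicated again.  Deterministic for a fixed seed.
    """
    result = PipelineResult(valid_sets=[])
    starts: List[CandidateSet] = []
    accepted: List[CandidateSet] = []
    batch_index = 0
    while (len(result.valid_sets) < target_valid
           and result.n_sampled < max_draws):
        batch_seed = (seed + 7919 * batch_index) % (2 ** 31)
        batch = sample_candidates(batch_size, batch_seed, bounds)
        batch_index += 1
        result.n_sampled += len(batch)
        for cand in batch:
            cand = check_conditions(cand, solver=screen_solver)
            if not cand.c2:
                continue
            result.n_oscillatory += 1
            before = len(starts)
            starts = dedupe(starts + [cand])
            if len(starts) == before:
                continue
            result.n_unique_starts += 1
            outcome = optimize_amplitude_match(cand, bounds, opt_config)
            if outcome.accepted:
                result.n_optimized_ok += 1
                accepted.append(outcome.candidate)
                result.valid_sets = dedupe(accepted)
                result.n_unique_valid = len(result.valid_sets)
                logger.info(
                    "pipeline: sampled=%d oscillatory=%d unique-starts=%d "
                    "optimized-ok=%d unique-valid=%d", result.n_sampled,
                    result.n_oscillatory, result.n_unique_starts,
                    result.n_optimized_ok, result.n_unique_valid)
                if len(result.valid_sets) >= target_valid:
                    break
    result.valid_sets = result.valid_sets[:target_valid]
    result.n_unique_valid = len(result.valid_sets)
    return result
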