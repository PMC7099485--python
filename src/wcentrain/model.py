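"""Extended Wilson-Cowan model of a neocortical microcircuit.

The circuit couples one excitatory population ``E`` to two inhibitory
subpopulations: a dendrite-targeting population ``I_dend`` (somatostatin-like,
purely subtractive inhibition) and a soma-targeting population ``I_soma``
(parvalbumin-like), whose inhibition of ``E`` interpolates between subtractive
and divisive according to the divisiveness parameter ``q`` in [0, 1].

The population input-output function is a logistic sigmoid extended with two
modulation channels: a subtractive modulation ``Theta`` shifts the curve along
the input axis, while a divisive modulation ``A`` scales down its slope and
maximal output,

    F(x, Theta, A) = alpha / (alpha + q A) *
                     [ logistic(alpha (x - (theta + Theta + (1 - q) A)))
                       - logistic(alpha theta)^(-1 complement) ],

where ``logistic(u) = 1 / (1 + exp(-u))`` and the subtracted constant
``1 / (1 + exp(alpha theta))`` makes ``F(0, 0, 0) = 0``.  At ``q = 0`` the
divisive channel collapses into a pure shift; at ``q = 1`` it is purely
divisive.  Saturation levels ``k = exp(alpha theta) / (1 + exp(alpha theta))``
bound every population's activity.

Activity evolves according to

    tau dE/dt      = -E      + (k_e - E)      F_e(w1 E + P(t), w2 I_dend, w3 I_soma)
    tau dI_dend/dt = -I_dend + (k_i - I_dend) F_i(w4 E, 0, 0)
    tau dI_soma/dt = -I_soma + (k_i - I_soma) F_i(w5 E, w6 I_dend + w7 I_soma, 0)

with connection weights ``w1..w7``, external drive ``P(t)`` and a single time
constant ``tau`` (seconds).  Mouse V1 connectivity constrains three weights to
ratios of ``w3``: ``w7 = w3``, ``w2 = 0.54 w3``, ``w6 = 0.33 w3``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence, Tuple

import numpy as np

from . import _integrate
from .errors import IntegrationError, ModelDomainError

__all__ = [
    "SigmoidConstants",
    "MicrocircuitParams",
    "PopulationState",
    "Trajectory",
    "SolverConfig",
    "DEFAULT_SIGMOID",
    "EXAMPLE_SET",
    "example_params",
    "modulated_sigmoid",
    "saturation_constant",
    "ode_rhs",
    "simulate",
]


@dataclass(frozen=True)
class SigmoidConstants:
    """Displacement and maximum-gain constants of the two sigmoid families.

    ``theta_*`` is the minimum displacement of the input-output curve along
    the input axis (its position with no subtractive inhibition); ``alpha_*``
    is the maximum gain (its slope with no divisive inhibition).  Defaults are
    the classical Wilson-Cowan values.
    """

    theta_e: float = 4.0
    theta_i: float = 3.7
    alpha_e: float = 1.3
    alpha_i: float = 2.0

    def __post_init__(self):
        for name in ("theta_e", "theta_i", "alpha_e", "alpha_i"):
            if not getattr(self, name) > 0:
                raise ModelDomainError(f"{name} must be strictly positive")

    @property
    def k_e(self) -> float:
        return saturation_constant(self.alpha_e, self.theta_e)

    @property
    def k_i(self) -> float:
        return saturation_constant(self.alpha_i, self.theta_i)


DEFAULT_SIGMOID = SigmoidConstants()

#: Weight ratios (relative to w3) implied by mouse-V1 connectivity:
#: w2 = 0.54 w3, w6 = 0.33 w3, w7 = w3.
W2_RATIO = 0.54
W6_RATIO = 0.33


@dataclass(frozen=True)
class MicrocircuitParams:
    """Full parameterization of the three-population microcircuit.

    Parameters are dimensionless except ``tau`` (seconds).  ``q`` is the
    divisiveness of the soma-targeting inhibition of E: 0 = purely
    subtractive, 1 = purely divisive.
    """

    P: float
    w1: float
    w2: float
    w3: float
    w4: float
    w5: float
    w6: float
    w7: float
    q: float
    tau: float = 0.05
    sigmoid: SigmoidConstants = field(default_factory=SigmoidConstants)

    def __post_init__(self):
        if not 0.0 <= self.q <= 1.0:
            raise ModelDomainError(f"q must lie in [0, 1], got {self.q}")
        if self.P < 0:
            raise ModelDomainError("P must be non-negative")
        for k in range(1, 8):
            if getattr(self, f"w{k}") < 0:
                raise ModelDomainError(f"w{k} must be non-negative")
        if not self.tau > 0:
            raise ModelDomainError("tau must be strictly positive")

    @classmethod
    def from_free_weights(cls, P: float, w1: float, w3: float, w4: float,
                          w5: float, q: float, tau: float = 0.05,
                          sigmoid: SigmoidConstants = DEFAULT_SIGMOID,
                          ) -> "MicrocircuitParams":
        """Build a parameter set from the five free parameters, filling
        ``w2``, ``w6``, ``w7`` through the connectivity ratio rule."""
        from .search import derive_dependent_weights

        w2, w6, w7 = derive_dependent_weights(w3)
        return cls(P=P, w1=w1, w2=w2, w3=w3, w4=w4, w5=w5, w6=w6, w7=w7,
                   q=q, tau=tau, sigmoid=sigmoid)

    def with_q(self, q: float) -> "MicrocircuitParams":
        return replace(self, q=q)

    def free_vector(self) -> np.ndarray:
        """The five independently sampled parameters (P, w1, w3, w4, w5)."""
        return np.array([self.P, self.w1, self.w3, self.w4, self.w5])


#: Reference parameter set used for the single-circuit experiments
#: (a valid set produced by the sampling/optimization procedure).
EXAMPLE_SET = {"P": 1.428, "w1": 24.368, "w3": 9.677, "w4": 27.249,
               "w5": 30.913}


def example_params(q: float, tau: float = 0.05) -> MicrocircuitParams:
    """The reference parameter set at divisiveness ``q`` (ratio-rule weights)."""
    return MicrocircuitParams.from_free_weights(q=q, tau=tau, **EXAMPLE_SET)


@dataclass(frozen=True)
class PopulationState:
    """Instantaneous activity of the three populations (dimensionless)."""

    E: float
    I_dend: float
    I_soma: float

    def as_array(self) -> np.ndarray:
        return np.array([self.E, self.I_dend, self.I_soma])


@dataclass
class Trajectory:
    """Uniformly sampled time series of the three populations and the drive.

    Attributes
    ----------
    t : (n,) array
        Strictly increasing, uniformly spaced times in seconds.
    states : (n, 3) array
        Columns are E, I_dend, I_soma.
    input : (n,) array
        Realized drive P(t) at each sample.
    """

    t: np.ndarray
    states: np.ndarray
    input: np.ndarray

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        self.input = np.asarray(self.input, dtype=float)
        if self.states.shape != (self.t.size, 3):
            raise ValueError("states must have shape (len(t), 3)")
        if self.input.shape != self.t.shape:
            raise ValueError("input must have the same length as t")
        if self.t.size >= 2:
            dts = np.diff(self.t)
            if dts.min() <= 0 or not np.allclose(dts, dts[0], rtol=1e-9,
                                                 atol=1e-12):
                raise ValueError("t must be strictly increasing and uniform")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    @property
    def E(self) -> np.ndarray:
        return self.states[:, 0]

    @property
    def I_dend(self) -> np.ndarray:
        return self.states[:, 1]

    @property
    def I_soma(self) -> np.ndarray:
        return self.states[:, 2]

    def state_at(self, index: int) -> PopulationState:
        E, Id, Is = self.states[index]
        return PopulationState(E=E, I_dend=Id, I_soma=Is)

    def index_of_time(self, time: float) -> int:
        """Index of the grid sample closest to ``time``."""
        i = int(round((time - self.t[0]) / self.dt))
        return min(max(i, 0), self.t.size - 1)

    def window(self, start: float, stop: float) -> "Trajectory":
        """Sub-trajectory covering [start, stop] (inclusive, grid-snapped)."""
        i0 = self.index_of_time(start)
        i1 = self.index_of_time(stop)
        return Trajectory(self.t[i0:i1 + 1], self.states[i0:i1 + 1],
                          self.input[i0:i1 + 1])


@dataclass(frozen=True)
class SolverConfig:
    """Numerical integration settings.

    ``dt`` is the uniform output step (seconds); the compiled fixed-step RK4
    kernel subdivides each output step into ``substeps`` internal steps.  The
    ``"rk45"`` method instead delegates to the adaptive Runge-Kutta 4(5)
    integrator of :func:`scipy.integrate.solve_ivp` at (``rtol``, ``atol``)
    and resamples onto the same grid; it is slower and serves as an
    independent accuracy check.
    """

    dt: float = 0.001
    substeps: int = 4
    method: str = "rk4"
    rtol: float = 1e-8
    atol: float = 1e-10

    def __post_init__(self):
        if self.dt <= 0:
            raise ModelDomainError("dt must be positive")
        if self.substeps < 1:
            raise ModelDomainError("substeps must be >= 1")
        if self.method not in ("rk4", "rk45"):
            raise ModelDomainError(f"unknown method {self.method!r}")


DEFAULT_SOLVER = SolverConfig()

#: Default initial condition; any state in the basin of the limit cycle works
#: because the settle window absorbs transients, but fixing one value makes
#: runs bit-reproducible.
DEFAULT_INITIAL_STATE = (0.1, 0.1, 0.1)


def saturation_constant(alpha: float, theta: float) -> float:
    """Saturation level ``k = exp(alpha theta) / (1 + exp(alpha theta))``.

    This is the supremum of the modulated sigmoid over its domain and hence
    an upper bound on the corresponding population's activity.  Strictly in
    (0.5, 1) for positive arguments.
    """
    if not (alpha > 0 and theta > 0):
        raise ModelDomainError("alpha and theta must be strictly positive")
    return 1.0 / (1.0 + math.exp(-alpha * theta))


def modulated_sigmoid(x: float, Theta: float, A: float, *, alpha: float,
                      theta: float, q: float) -> float:
    """Input-output function with subtractive and divisive modulation.

    Parameters
    ----------
    x : float
        Net excitatory drive (non-negative).
    Theta : float
        Subtractive modulation: shifts the curve to higher inputs.
    A : float
        Divisive modulation: a fraction ``q`` of it divides the gain and
        maximal output, the remaining ``1 - q`` acts as an additional shift.
    alpha, theta : float
        Maximum gain and minimum displacement of the underlying sigmoid.
    q : float
        Divisiveness in [0, 1].

    Returns
    -------
    float
        Firing-rate value, zero at ``x = 0`` when unmodulated and bounded
        above by ``saturation_constant(alpha, theta)``.
    """
    if x < 0 or Theta < 0 or A < 0:
        raise ModelDomainError("x, Theta and A must be non-negative")
    if not 0.0 <= q <= 1.0:
        raise ModelDomainError("q must lie in [0, 1]")
    if not (alpha > 0 and theta > 0):
        raise ModelDomainError("alpha and theta must be strictly positive")
    return float(_integrate._sigmoid_mod(x, Theta, A, alpha, theta, q))


def ode_rhs(state: PopulationState | Sequence[float], input_value: float,
            params: MicrocircuitParams) -> Tuple[float, float, float]:
    """Time derivatives (dE/dt, dI_dend/dt, dI_soma/dt) of the circuit.

    E receives recurrent drive ``w1 E + P(t)``, subtractive inhibition
    ``w2 I_dend`` and (partly) divisive inhibition ``w3 I_soma``; I_dend
    receives ``w4 E`` unmodulated; I_soma receives ``w5 E`` with subtractive
    inhibition ``w6 I_dend + w7 I_soma``.
    """
    if isinstance(state, PopulationState):
        E, Id, Is = state.E, state.I_dend, state.I_soma
    else:
        E, Id, Is = state
    if not all(map(math.isfinite, (E, Id, Is))):
        raise ModelDomainError("state must be finite")
    if input_value < 0:
        raise ModelDomainError("input_value must be non-negative")
    sg = params.sigmoid
    return _integrate._rhs(
        E, Id, Is, input_value, params.w1, params.w2, params.w3, params.w4,
        params.w5, params.w6, params.w7, params.q, params.tau,
        sg.theta_e, sg.theta_i, sg.alpha_e, sg.alpha_i, sg.k_e, sg.k_i)


def _kernel_args(params: MicrocircuitParams):
    sg = params.sigmoid
    return (params.P, params.w1, params.w2, params.w3, params.w4, params.w5,
            params.w6, params.w7, params.q, params.tau, sg.theta_e,
            sg.theta_i, sg.alpha_e, sg.alpha_i, sg.k_e, sg.k_i)


def simulate(params: MicrocircuitParams, duration: float,
             solver: SolverConfig = DEFAULT_SOLVER,
             y0: Sequence[float] = DEFAULT_INITIAL_STATE,
             t_switch: float = math.inf, Lambda: float = 0.0,
             f_in: float = 1.0, phi0: float = 0.0,
             t_start: float = 0.0) -> Trajectory:
    """Integrate the circuit under a constant-then-sinusoidal drive.

    The realized input is ``P`` for ``t < t_switch`` and
    ``P + Lambda sin(2 pi f_in (t - t_switch) + phi0)`` afterwards; with the
    default ``t_switch = inf`` the drive stays constant.  Use
    :func:`wcentrain.drive.run_protocol` to realize a drive with a controlled
    initial phase difference.

    Raises
    ------
    IntegrationError
        If a non-finite state is encountered (names the failure time).
    """
    n_out = int(round(duration / solver.dt))
    if n_out < 1:
        raise ModelDomainError("duration must cover at least one output step")
    y0 = np.asarray(y0, dtype=float)
    if solver.method == "rk4":
        states, inputs, fail = _integrate.integrate_rk4(
            y0, t_start, n_out, solver.dt, solver.substeps,
            *_kernel_args(params), t_switch, Lambda, f_in, phi0)
        if fail >= 0:
            raise IntegrationError(t_start + fail * solver.dt)
    else:
        states, inputs = _simulate_rk45(params, y0, t_start, n_out, solver,
                                        t_switch, Lambda, f_in, phi0)
    t = t_start + solver.dt * np.arange(n_out + 1)
    return Trajectory(t=t, states=states, input=inputs)


def _simulate_rk45(params, y0, t_start, n_out, solver, t_switch, Lambda,
                   f_in, phi0):
    """Adaptive-integrator reference path (scipy RK45, dense output)."""
    from scipy.integrate import solve_ivp

    args = _kernel_args(params)

    def rhs(t, y):
        p_t = _integrate._drive_value(t, params.P, t_switch, Lambda, f_in,
                                      phi0)
        return _integrate._rhs(y[0], y[1], y[2], p_t, *args[1:])

    t_end = t_start + n_out * solver.dt
    t_eval = t_start + solver.dt * np.arange(n_out + 1)
    # Integrate up to the drive discontinuity and onwards separately so the
    # adaptive stepper never straddles it.
    breakpoints = [t_start]
    if t_start < t_switch < t_end:
        breakpoints.append(t_switch)
    breakpoints.append(t_end)
    states = np.empty((n_out + 1, 3))
    y = np.asarray(y0, dtype=float)
    for a, b in zip(breakpoints[:-1], breakpoints[1:]):
        mask = (t_eval >= a - 1e-12) & (t_eval <= b + 1e-12)
        sol = solve_ivp(rhs, (a, b), y, method="RK45", rtol=solver.rtol,
                        atol=solver.atol, t_eval=t_eval[mask])
        if not sol.success:
            raise IntegrationError(float(sol.t[-1]) if sol.t.size else a)
        states[mask] = sol.y.T
        y = sol.y[:, -1]
    if not np.all(np.isfinite(states)):
        bad = int(np.argmax(~np.all(np.isfinite(states), axis=1)))
        raise IntegrationError(float(t_eval[bad]))
    inputs = np.array([_integrate._drive_value(t, params.P, t_switch, Lambda,
                                               f_in, phi0) for t in t_eval])
    return states, inputs
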