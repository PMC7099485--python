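"""Model core: modulated sigmoid, saturation, ODE right-hand side, solver."""

import math

import numpy as np
import pytest
from scipy.integrate import odeint
from scipy.optimize import fsolve

from wcentrain.errors import ModelDomainError
from wcentrain.model import (MicrocircuitParams, PopulationState,
                             SigmoidConstants, SolverConfig, Trajectory,
                             modulated_sigmoid, ode_rhs,
                             saturation_constant, simulate)


class TestSaturationConstant:
    @pytest.mark.parametrize("alpha,theta,expected", [
        # closed form exp(a t)/(1+exp(a t)) evaluated with 20-digit
        # symbolic arithmetic
        (1.3, 4.0, 0.99451370110054959467),
        (2.0, 3.7, 0.99938912064056559879),
    ])
    def test_reference_values(self, alpha, theta, expected):
        assert saturation_constant(alpha, theta) == pytest.approx(
            expected, abs=1e-12)

    def test_small_gain_limit_is_half(self):
        assert saturation_constant(1e-9, 1.0) == pytest.approx(0.5, abs=1e-8)

    def test_strictly_between_half_and_one(self):
        for alpha, theta in [(0.1, 0.1), (1.0, 1.0), (2.0, 5.0)]:
            k = saturation_constant(alpha, theta)
            assert 0.5 < k < 1.0

    @pytest.mark.parametrize("alpha,theta", [(0, 1), (-1, 1), (1, 0)])
    def test_domain_errors(self, alpha, theta):
        with pytest.raises(ModelDomainError):
            saturation_constant(alpha, theta)


class TestModulatedSigmoid:
    def test_midpoint_identity(self):
        # unmodulated input at the displacement theta puts the logistic at
        # its midpoint, so F = 1/2 - 1/(1 + e^(alpha theta))
        for q in (0.0, 0.37, 1.0):
            val = modulated_sigmoid(4.0, 0.0, 0.0, alpha=1.3, theta=4.0, q=q)
            assert val == pytest.approx(0.5 - 1.0 / (1 + math.exp(5.2)),
                                        abs=1e-14)

    def test_vanishes_at_zero_input(self):
        for alpha, theta, q in [(1.3, 4.0, 0.0), (2.0, 3.7, 1.0),
                                (0.5, 1.0, 0.5)]:
            assert modulated_sigmoid(0.0, 0.0, 0.0, alpha=alpha, theta=theta,
                                     q=q) == pytest.approx(0.0, abs=1e-15)

    def test_q0_divisive_collapses_to_shift(self):
        # at q = 0 the divisive channel acts as a pure displacement
        for x in np.linspace(0, 12, 7):
            for Theta in (0.0, 1.5, 4.0):
                for A in (0.0, 2.0, 5.0):
                    a = modulated_sigmoid(x, Theta, A, alpha=1.3, theta=4.0,
                                          q=0.0)
                    b = modulated_sigmoid(x, Theta + A, 0.0, alpha=1.3,
                                          theta=4.0, q=0.0)
                    assert a == pytest.approx(b, abs=1e-14)

    def test_approaches_saturation_constant(self):
        for alpha, theta in [(1.3, 4.0), (2.0, 3.7)]:
            val = modulated_sigmoid(10 * theta, 0.0, 0.0, alpha=alpha,
                                    theta=theta, q=0.5)
            assert val == pytest.approx(saturation_constant(alpha, theta),
                                        abs=1e-6)

    def test_bounded_by_saturation(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            x, Theta, A = rng.uniform(0, 20, 3)
            q = rng.uniform(0, 1)
            val = modulated_sigmoid(x, Theta, A, alpha=1.3, theta=4.0, q=q)
            assert val < saturation_constant(1.3, 4.0)

    @pytest.mark.parametrize("kwargs", [
        {"x": -1.0}, {"Theta": -0.1}, {"A": -0.1}, {"q": 1.5}, {"q": -0.1},
    ])
    def test_domain_errors(self, kwargs):
        args = {"x": 1.0, "Theta": 0.0, "A": 0.0, "q": 0.5}
        args.update(kwargs)
        with pytest.raises(ModelDomainError):
            modulated_sigmoid(args["x"], args["Theta"], args["A"],
                              alpha=1.3, theta=4.0, q=args["q"])


class TestOdeRhs:
    def test_zero_state(self, example_q0):
        p = example_q0
        sg = p.sigmoid
        dE, dId, dIs = ode_rhs((0.0, 0.0, 0.0), p.P, p)
        expected_dE = sg.k_e * modulated_sigmoid(
            p.P, 0.0, 0.0, alpha=sg.alpha_e, theta=sg.theta_e, q=p.q) / p.tau
        assert dE == pytest.approx(expected_dE, rel=1e-12)
        # F_i(0, 0, 0) = 0 forces both inhibitory derivatives to zero
        assert dId == pytest.approx(0.0, abs=1e-15)
        assert dIs == pytest.approx(0.0, abs=1e-15)

    def test_tau_scales_all_components(self, example_q1):
        p = example_q1
        p2 = MicrocircuitParams(P=p.P, w1=p.w1, w2=p.w2, w3=p.w3, w4=p.w4,
                                w5=p.w5, w6=p.w6, w7=p.w7, q=p.q,
                                tau=2 * p.tau, sigmoid=p.sigmoid)
        state = (0.3, 0.2, 0.25)
        d1 = np.array(ode_rhs(state, p.P, p))
        d2 = np.array(ode_rhs(state, p.P, p2))
        np.testing.assert_allclose(d2, d1 / 2, rtol=1e-12)

    def test_fixed_point_has_zero_derivative(self, example_q0):
        p = example_q0

        def f(y):
            return ode_rhs(tuple(y), p.P, p)

        root = fsolve(f, [0.2, 0.2, 0.2], full_output=False)
        assert np.max(np.abs(ode_rhs(tuple(root), p.P, p))) < 1e-8

    def test_accepts_population_state(self, example_q0):
        a = ode_rhs(PopulationState(0.1, 0.1, 0.1), 1.0, example_q0)
        b = ode_rhs((0.1, 0.1, 0.1), 1.0, example_q0)
        assert a == b


class TestSimulate:
    def test_decay_to_origin_matches_reference_integrator(self):
        # all couplings off, no drive: every population relaxes to zero;
        # cross-checked against an independent stiff integrator
        p = MicrocircuitParams(P=0.0, w1=0, w2=0, w3=0, w4=0, w5=0, w6=0,
                               w7=0, q=0.0)
        traj = simulate(p, 2.0, y0=(0.4, 0.3, 0.2))
        assert np.max(np.abs(traj.states[-1])) < 1e-6

        def rhs(y, t):
            return ode_rhs(tuple(y), 0.0, p)

        ref = odeint(rhs, [0.4, 0.3, 0.2], traj.t, rtol=1e-10, atol=1e-12)
        assert np.max(np.abs(ref - traj.states)) < 1e-7

    def test_bounded_dynamics(self):
        rng = np.random.default_rng(3)
        sg = SigmoidConstants()
        for _ in range(5):
            p = MicrocircuitParams.from_free_weights(
                P=rng.uniform(0, 5), w1=rng.uniform(0, 35),
                w3=rng.uniform(0, 35), w4=rng.uniform(0, 35),
                w5=rng.uniform(0, 35), q=rng.uniform(0, 1))
            y0 = (rng.uniform(0, sg.k_e), rng.uniform(0, sg.k_i),
                  rng.uniform(0, sg.k_i))
            traj = simulate(p, 5.0, y0=y0)
            assert traj.E.max() < sg.k_e + 1e-6
            assert traj.I_dend.max() < sg.k_i + 1e-6
            assert traj.I_soma.max() < sg.k_i + 1e-6

    def test_solver_independence(self, example_q0):
        base = simulate(example_q0, 20.0, solver=SolverConfig(substeps=4))
        fine = simulate(example_q0, 20.0, solver=SolverConfig(substeps=8))
        assert np.max(np.abs(base.E - fine.E)) < 1e-4
        adaptive = simulate(example_q0, 20.0,
                            solver=SolverConfig(method="rk45"))
        assert np.max(np.abs(base.E - adaptive.E)) < 1e-4

    def test_q0_matches_classic_two_population_reduction(self):
        # with w3 = 0 and the soma-targeting feedback silenced, E and
        # I_dend follow the classic two-sigmoid excitatory-inhibitory
        # system; oracle integrated independently
        p = MicrocircuitParams(P=1.428, w1=24.368, w2=5.225, w3=0.0,
                               w4=27.249, w5=0.0, w6=0.0, w7=0.0, q=0.0)
        sg = p.sigmoid

        def logistic_pair(x, alpha, theta):
            return (1 / (1 + np.exp(-alpha * (x - theta)))
                    - 1 / (1 + np.exp(alpha * theta)))

        def oracle(y, t):
            E, I = y
            dE = (-E + (sg.k_e - E) * logistic_pair(
                p.w1 * E + p.P - p.w2 * I, sg.alpha_e, sg.theta_e)) / p.tau
            dI = (-I + (sg.k_i - I) * logistic_pair(
                p.w4 * E, sg.alpha_i, sg.theta_i)) / p.tau
            return [dE, dI]

        traj = simulate(p, 5.0, y0=(0.1, 0.1, 0.1))
        ref = odeint(oracle, [0.1, 0.1], traj.t, rtol=1e-10, atol=1e-12)
        assert np.max(np.abs(traj.E - ref[:, 0])) < 1e-5
        assert np.max(np.abs(traj.I_dend - ref[:, 1])) < 1e-5


class TestTypes:
    def test_ratio_rule_invariants(self):
        p = MicrocircuitParams.from_free_weights(P=1.0, w1=10, w3=9.677,
                                                 w4=5, w5=5, q=0.5)
        assert abs(p.w7 - p.w3) < 1e-9
        assert abs(p.w2 - 0.54 * p.w3) < 1e-9
        assert abs(p.w6 - 0.33 * p.w3) < 1e-9

    @pytest.mark.parametrize("kwargs", [
        {"q": 1.5}, {"q": -0.1}, {"P": -1.0}, {"w1": -2.0}, {"tau": 0.0},
    ])
    def test_params_validation(self, kwargs):
        base = dict(P=1.0, w1=1, w2=1, w3=1, w4=1, w5=1, w6=1, w7=1, q=0.5,
                    tau=0.05)
        base.update(kwargs)
        with pytest.raises(ModelDomainError):
            MicrocircuitParams(**base)

    def test_trajectory_validation(self):
        t = np.array([0.0, 0.001, 0.003])  # non-uniform
        with pytest.raises(ValueError):
            Trajectory(t=t, states=np.zeros((3, 3)), input=np.zeros(3))
        with pytest.raises(ValueError):
            Trajectory(t=np.arange(3) * 0.001, states=np.zeros((2, 3)),
                       input=np.zeros(3))

    def test_example_set_frequency_split(self, example_candidate):
        # the reference set oscillates faster fully subtractive than fully
        # divisive, both within the theta band
        c = example_candidate
        assert c.all_conditions
        assert c.f_q0 > c.f_q1
        assert 4.0 < c.f_q1 < c.f_q0 < 8.0
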