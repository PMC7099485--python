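"""Compiled integration kernels.

The three-population system is smooth and non-stiff, so a classical
fixed-step Runge-Kutta 4 scheme with a sub-millisecond internal step is both
accurate (global error well below 1e-6 on the reference parameter set, see
the solver-independence test) and fast enough for the parameter-space
screening, which integrates the model tens of thousands of times.

All kernels are nopython-compiled; parameters are passed as scalars so a
single specialization serves every parameter set.
"""

import numpy as np
from numba import njit

TWO_PI = 2.0 * np.pi


@njit(cache=True)
def _sigmoid_mod(x, Th, A, alpha, theta, q):
    # Modulated input-output function; no domain checks here (the raw ODE is
    # integrated as written, so transient negative excursions are allowed).
    return (alpha / (alpha + q * A)) * (
        1.0 / (1.0 + np.exp(-alpha * (x - (theta + Th + (1.0 - q) * A))))
        - 1.0 / (1.0 + np.exp(alpha * theta))
    )


@njit(cache=True)
def _drive_value(t, P, t_switch, lam, f_in, phi0):
    if t < t_switch:
        return P
    return P + lam * np.sin(TWO_PI * f_in * (t - t_switch) + phi0)


@njit(cache=True)
def _rhs(E, Id, Is, p_t, w1, w2, w3, w4, w5, w6, w7, q, tau,
         th_e, th_i, al_e, al_i, ke, ki):
    dE = (-E + (ke - E) * _sigmoid_mod(w1 * E + p_t, w2 * Id, w3 * Is,
                                       al_e, th_e, q)) / tau
    dId = (-Id + (ki - Id) * _sigmoid_mod(w4 * E, 0.0, 0.0,
                                          al_i, th_i, q)) / tau
    dIs = (-Is + (ki - Is) * _sigmoid_mod(w5 * E, w6 * Id + w7 * Is, 0.0,
                                          al_i, th_i, q)) / tau
    return dE, dId, dIs


@njit(cache=True)
def integrate_rk4(y0, t_start, n_out, h_out, substeps,
                  P, w1, w2, w3, w4, w5, w6, w7, q, tau,
                  th_e, th_i, al_e, al_i, ke, ki,
                  t_switch, lam, f_in, phi0):
    """Integrate the microcircuit ODE on a uniform output grid.

    Returns
    -------
    states : (n_out + 1, 3) array
        E, I_dend, I_soma at each output sample.
    inputs : (n_out + 1,) array
        Realized drive P(t) at each output sample.
    fail : int
        Index of the first non-finite output sample, or -1 on success.
    """
    states = np.empty((n_out + 1, 3))
    inputs = np.empty(n_out + 1)
    h = h_out / substeps
    E, Id, Is = y0[0], y0[1], y0[2]
    states[0, 0] = E
    states[0, 1] = Id
    states[0, 2] = Is
    inputs[0] = _drive_value(t_start, P, t_switch, lam, f_in, phi0)
    for i in range(n_out):
        t_base = t_start + i * h_out
        for s in range(substeps):
            t = t_base + s * h
            p1 = _drive_value(t, P, t_switch, lam, f_in, phi0)
            p2 = _drive_value(t + 0.5 * h, P, t_switch, lam, f_in, phi0)
            p3 = _drive_value(t + h, P, t_switch, lam, f_in, phi0)
            k1 = _rhs(E, Id, Is, p1, w1, w2, w3, w4, w5, w6, w7, q, tau,
                      th_e, th_i, al_e, al_i, ke, ki)
            k2 = _rhs(E + 0.5 * h * k1[0], Id + 0.5 * h * k1[1],
                      Is + 0.5 * h * k1[2], p2, w1, w2, w3, w4, w5, w6, w7,
                      q, tau, th_e, th_i, al_e, al_i, ke, ki)
            k3 = _rhs(E + 0.5 * h * k2[0], Id + 0.5 * h * k2[1],
                      Is + 0.5 * h * k2[2], p2, w1, w2, w3, w4, w5, w6, w7,
                      q, tau, th_e, th_i, al_e, al_i, ke, ki)
            k4 = _rhs(E + h * k3[0], Id + h * k3[1], Is + h * k3[2], p3,
                      w1, w2, w3, w4, w5, w6, w7, q, tau,
                      th_e, th_i, al_e, al_i, ke, ki)
            E = E + (h / 6.0) * (k1[0] + 2.0 * k2[0] + 2.0 * k3[0] + k4[0])
            Id = Id + (h / 6.0) * (k1[1] + 2.0 * k2[1] + 2.0 * k3[1] + k4[1])
            Is = Is + (h / 6.0) * (k1[2] + 2.0 * k2[2] + 2.0 * k3[2] + k4[2])
        states[i + 1, 0] = E
        states[i + 1, 1] = Id
        states[i + 1, 2] = Is
        inputs[i + 1] = _drive_value(t_base + h_out, P, t_switch, lam,
                                     f_in, phi0)
        if not (np.isfinite(E) and np.isfinite(Id) and np.isfinite(Is)):
            return states, inputs, i + 1
    return states, inputs, -1
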