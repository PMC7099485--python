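"""Synthetic trajectories with planted spectral and transient structure.

These generators build `Trajectory` objects whose ground truth is known by
construction — component sinusoids with chosen frequencies and amplitudes, a
planted transient of known length, optional Gaussian noise — and are the
fixtures against which the entrainment metrics are validated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .errors import ModelDomainError
from .model import Trajectory

__all__ = ["SyntheticTrajectorySpec", "generate_synthetic_trajectory"]


@dataclass(frozen=True)
class SyntheticTrajectorySpec:
    """Recipe for a synthetic trajectory.

    ``components`` are (frequency Hz, amplitude, phase rad) sinusoids summed
    into every state channel (the two inhibitory channels are scaled copies
    of E so that limit-cycle membership sees a consistent 3-D orbit).  A
    planted transient adds a decaying perturbation that is switched off
    abruptly ``transient_length`` seconds after ``transient_start``, so the
    true convergence instant is known exactly.
    """

    components: Tuple[Tuple[float, float, float], ...]
    duration: float = 20.0
    dt: float = 0.001
    offset: float = 0.5
    noise_sigma: float = 0.0
    transient_start: float = 10.0
    transient_length: Optional[float] = None
    transient_amplitude: float = 0.2
    transient_decay: float = 1.0
    channel_scales: Tuple[float, float, float] = (1.0, 0.8, 1.2)
    #: Per-channel phase lags (radians) applied to every component, so the
    #: three channels trace a genuine closed loop in state space rather
    #: than a degenerate line segment.
    channel_lags: Tuple[float, float, float] = (0.0, 1.0, 2.0)
    baseline_input: float = 1.0

    def __post_init__(self):
        if self.duration <= 0 or self.dt <= 0:
            raise ModelDomainError("duration and dt must be positive")
        nyquist = 0.5 / self.dt
        for f, _, _ in self.components:
            if f >= nyquist:
                raise ModelDomainError(
                    f"component frequency {f} Hz is at or above the Nyquist "
                    f"frequency {nyquist} Hz")


def generate_synthetic_trajectory(spec: SyntheticTrajectorySpec,
                                  seed: int = 0) -> Trajectory:
    """Materialize a spec as a `Trajectory` (seeded, reproducible)."""
    rng = np.random.default_rng(seed)
    n = int(round(spec.duration / spec.dt)) + 1
    t = spec.dt * np.arange(n)
    channels = []
    for scale, lag in zip(spec.channel_scales, spec.channel_lags):
        signal = np.full(n, spec.offset)
        for f, a, ph in spec.components:
            signal = signal + a * np.sin(2 * np.pi * f * t + ph - lag)
        channels.append(scale * signal)
    states = np.column_stack(channels)
    if spec.transient_length is not None:
        # decaying bump active on [start, start + length), cut off abruptly
        # so the last above-tolerance sample sits just before the cutoff
        active = (t >= spec.transient_start) & \
                 (t < spec.transient_start + spec.transient_length)
        decay = np.exp(-(t - spec.transient_start) / spec.transient_decay)
        bump = np.where(active, spec.transient_amplitude * decay, 0.0)
        states = states + np.column_stack(
            [s * bump for s in spec.channel_scales])
    if spec.noise_sigma > 0:
        states = states + rng.normal(
            0.0, spec.noise_sigma, size=states.shape) * np.asarray(
            spec.channel_scales)
    inp = np.full(n, spec.baseline_input)
    return Trajectory(t=t, states=states, input=inp)
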