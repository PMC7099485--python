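"""Entrainment quantification.

Two complementary measures characterize a run:

* **Entrainment index** — the proportion of normalized spectral peak power
  concentrated at the drive frequency ``f_in``, computed from the periodogram
  of E(t) after the trajectory has converged to its final limit cycle.
  Harmonic peaks (integer multiples of a stronger peak) are removed before
  normalization so the index does not depend on how sinusoidal the waveform
  is; the peak at ``f_in`` itself is always preserved so subharmonic (1:2)
  entrainment remains detectable.  The index ranges from 0 (no entrainment)
  to 1 (complete entrainment).

* **Convergence time** — the time elapsed between drive onset and arrival on
  the final limit cycle.  The limit cycle is the set of tolerance-unique
  3-D state points visited during the last 3 s of the run; scanning backward
  from 3 s before the end, the first state that is not a member of that set
  (at a wider tolerance) marks the end of the transient.  It is reported only
  for complete entrainment (index > 0.98), which always reflects 1:1 locking.

Tolerances follow the convention of tolerance-based set operations in
common numerical environments: by default they are *relative*, scaled by
the largest absolute coordinate in the compared data, with an absolute
mode available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.signal import find_peaks
from scipy.spatial import cKDTree

from .errors import (EmptySpectrumError, InsufficientDataError,
                     NoOscillationError, UndefinedPhaseError)
from .model import Trajectory

__all__ = [
    "SpectrumPeaks",
    "EntrainmentResult",
    "OSCILLATION_THRESHOLD",
    "FULL_ENTRAINMENT_THRESHOLD",
    "power_spectrum",
    "detect_peaks",
    "prune_harmonics",
    "entrainment_index",
    "convergence_time",
    "natural_frequency",
    "peak_to_peak",
    "final_phase_difference",
    "evaluate_entrainment",
]

#: Peak-to-peak amplitude of E below which a run is treated as non-oscillatory.
#: Chosen an order of magnitude above solver noise and an order below typical
#: limit-cycle amplitudes.
OSCILLATION_THRESHOLD = 0.01

#: Entrainment-index threshold for "complete or almost complete" entrainment;
#: only such runs get a convergence time.
FULL_ENTRAINMENT_THRESHOLD = 0.98

#: Limit-cycle uniqueness and membership tolerances (relative by default).
UNIQUE_TOL = 0.001
MEMBER_TOL = 0.01

#: Local maxima below this fraction of the strongest peak are ignored.
PEAK_POWER_FLOOR = 1e-5

#: Harmonic multipliers checked during pruning.
HARMONIC_RANGE = range(2, 11)

#: Analysis window (s) at the end of a run used for the limit cycle, the
#: natural frequency and steady-state amplitudes.
STEADY_WINDOW = 3.0


@dataclass(frozen=True)
class SpectrumPeaks:
    """Pruned, normalized spectral peak list.

    ``peaks`` holds (frequency in Hz, normalized power) sorted by descending
    power; the normalized powers sum to 1.  ``f_in_index`` points at the peak
    matching the drive frequency, or is None when no peak lies within one
    frequency bin of it.  ``bin_width`` is the frequency resolution.
    """

    peaks: Tuple[Tuple[float, float], ...]
    f_in_index: Optional[int]
    bin_width: float

    @property
    def frequencies(self) -> np.ndarray:
        return np.array([f for f, _ in self.peaks])

    @property
    def powers(self) -> np.ndarray:
        return np.array([p for _, p in self.peaks])


@dataclass(frozen=True)
class EntrainmentResult:
    """Entrainment metrics for a single run.

    ``convergence_time`` (seconds since drive onset) is None unless
    ``index`` exceeds the complete-entrainment threshold; ``converged`` is
    False when the final window of the run is not yet periodic, in which
    case the convergence time is undefined as well.
    """

    index: float
    convergence_time: Optional[float]
    converged: bool
    final_phase_diff: Optional[float] = None
    spectrum: Optional[SpectrumPeaks] = None

    def __post_init__(self):
        if not 0.0 <= self.index <= 1.0 + 1e-12:
            raise ValueError("entrainment index must lie in [0, 1]")


def peak_to_peak(trajectory: Trajectory, variable: str = "E",
                 window: Optional[Tuple[float, float]] = None) -> float:
    """Max minus min of one population's activity over a time window."""
    if variable not in ("E", "I_dend", "I_soma"):
        raise ValueError(f"unknown variable {variable!r}")
    traj = trajectory if window is None else trajectory.window(*window)
    x = getattr(traj, variable)
    return float(x.max() - x.min())


def power_spectrum(signal: np.ndarray, dt: float,
                   ) -> Tuple[np.ndarray, np.ndarray]:
    """Periodogram of a mean-subtracted, uniformly sampled segment.

    Power is the squared magnitude of the discrete Fourier transform (no
    taper); frequency resolution is the reciprocal segment duration.

    Raises
    ------
    InsufficientDataError
        If the segment is shorter than 2 s.
    """
    signal = np.asarray(signal, dtype=float)
    if signal.size * dt < 2.0:
        raise InsufficientDataError(
            f"segment of {signal.size * dt:.3f} s is shorter than the 2 s "
            "minimum for spectral analysis")
    x = signal - signal.mean()
    spec = np.abs(np.fft.rfft(x)) ** 2
    freqs = np.fft.rfftfreq(x.size, d=dt)
    return freqs, spec


def detect_peaks(freqs: np.ndarray, power: np.ndarray,
                 floor: float = PEAK_POWER_FLOOR,
                 ) -> List[Tuple[float, float]]:
    """Local maxima of a periodogram above ``floor`` x the strongest peak,
    sorted by descending power."""
    idx, _ = find_peaks(power)
    if idx.size == 0:
        return []
    keep = power[idx] >= floor * power[idx].max()
    idx = idx[keep]
    order = np.argsort(power[idx])[::-1]
    return [(float(freqs[i]), float(power[i])) for i in idx[order]]


def prune_harmonics(peaks: Sequence[Tuple[float, float]], f_in: float,
                    bin_width: float) -> SpectrumPeaks:
    """Remove harmonic peaks and renormalize the survivors.

    A peak whose frequency is an integer multiple (n >= 2, within one
    frequency bin) of a stronger retained peak's frequency is removed —
    unless it lies within one bin of the drive frequency ``f_in``, which is
    always preserved so subharmonic entrainment stays detectable.  Retained
    powers are renormalized to sum to 1.

    ``peaks`` must be sorted by descending power.
    """
    if len(peaks) == 0:
        raise EmptySpectrumError("no spectral peaks to prune")
    retained: List[Tuple[float, float]] = []
    for f, p in peaks:
        is_drive = abs(f - f_in) <= bin_width
        harmonic = False
        if not is_drive:
            for fr, _ in retained:
                if any(abs(f - n * fr) <= bin_width for n in HARMONIC_RANGE):
                    harmonic = True
                    break
        if not harmonic:
            retained.append((f, p))
    total = sum(p for _, p in retained)
    normalized = tuple((f, p / total) for f, p in retained)
    f_in_index = None
    for i, (f, _) in enumerate(normalized):
        if abs(f - f_in) <= bin_width:
            f_in_index = i
            break
    return SpectrumPeaks(peaks=normalized, f_in_index=f_in_index,
                         bin_width=bin_width)


def entrainment_index(spectrum: SpectrumPeaks, f_in: float) -> float:
    """Normalized power of the retained peak at the drive frequency
    (0 when no peak lies within one frequency bin of ``f_in``)."""
    for f, p in spectrum.peaks:
        if abs(f - f_in) <= spectrum.bin_width:
            return float(min(p, 1.0))
    return 0.0


def _tolerance_scale(points: np.ndarray, mode: str) -> float:
    if mode == "absolute":
        return 1.0
    if mode == "relative":
        return float(np.max(np.abs(points))) or 1.0
    raise ValueError(f"unknown tolerance mode {mode!r}")


def _unique_points(points: np.ndarray, atol: float) -> np.ndarray:
    """Greedy tolerance-unique subset (Chebyshev metric), in scan order."""
    kept = np.empty_like(points)
    n_kept = 0
    for p in points:
        if n_kept == 0 or np.min(
                np.max(np.abs(kept[:n_kept] - p), axis=1)) > atol:
            kept[n_kept] = p
            n_kept += 1
    return kept[:n_kept]


def _estimate_period(E: np.ndarray, dt: float) -> Optional[float]:
    pk, _ = find_peaks(E)
    if pk.size < 3:
        return None
    return float(np.mean(np.diff(pk)) * dt)


def convergence_time(trajectory: Trajectory, switch_time: float,
                     unique_tol: float = UNIQUE_TOL,
                     member_tol: float = MEMBER_TOL,
                     tolerance_mode: str = "relative",
                     window: float = STEADY_WINDOW,
                     ) -> Tuple[Optional[float], bool]:
    """Time for the 3-D state to converge to its final limit cycle.

    The limit cycle is the tolerance-unique set of state points over the
    last ``window`` seconds of the run.  Scanning backward from the start of
    that window, the first state that fails limit-cycle membership marks the
    end of the transient; the returned time is that instant minus
    ``switch_time``, clamped at 0.  A constant trajectory counts as a
    (degenerate) cycle and converges immediately.

    Returns
    -------
    (time, converged)
        ``converged`` is False when the final window is not yet periodic
        (successive-cycle deviation above the membership tolerance); the
        time is then None.
    """
    t_end = trajectory.t[-1]
    tail = trajectory.window(t_end - window, t_end)
    pts = tail.states
    scale = _tolerance_scale(pts, tolerance_mode)

    # Periodicity check of the final window: compare successive cycles.
    period = _estimate_period(tail.E, trajectory.dt)
    if peak_to_peak(tail) > OSCILLATION_THRESHOLD:
        if period is None:
            return None, False
        lag = int(round(period / trajectory.dt))
        if lag > 0 and lag < pts.shape[0]:
            dev = np.max(np.abs(pts[lag:] - pts[:-lag]))
            if dev > member_tol * scale:
                return None, False

    cycle = _unique_points(pts, unique_tol * scale)
    tree = cKDTree(cycle)
    i_tail = trajectory.index_of_time(t_end - window)
    i_switch = trajectory.index_of_time(switch_time)
    pre = trajectory.states[:i_tail]
    dist, _ = tree.query(pre, k=1, p=np.inf,
                         distance_upper_bound=member_tol * scale)
    outside = np.nonzero(np.isinf(dist))[0]
    if outside.size == 0:
        return 0.0, True
    last_outside = int(outside[-1])
    t_conv = trajectory.t[last_outside]
    return max(0.0, float(t_conv - switch_time)), True


def _integer_cycles_slice(E: np.ndarray, dt: float,
                          f_ref: Optional[float]) -> np.ndarray:
    """Crop a segment to an integer number of cycles of ``f_ref`` to
    suppress spectral leakage at that frequency and its harmonics."""
    if f_ref is None or f_ref <= 0:
        return E
    period_n = 1.0 / (f_ref * dt)
    n_cycles = int(E.size / period_n)
    n = int(round(n_cycles * period_n))
    if n_cycles < 2 or n < 2 or n > E.size:
        return E
    return E[:n]


def natural_frequency(trajectory: Trajectory,
                      window: float = STEADY_WINDOW,
                      agreement_tol: float = 0.2) -> float:
    """Intrinsic oscillation frequency under constant drive (Hz).

    Estimated as the dominant periodogram peak of E(t) over the final
    analysis window, refined by the mean inter-peak interval; the two
    estimates must agree within ``agreement_tol`` Hz.

    Raises
    ------
    NoOscillationError
        If there is no sustained oscillation or the two estimates disagree
        (e.g. aperiodic activity).
    """
    t_end = trajectory.t[-1]
    tail = trajectory.window(t_end - window, t_end)
    if peak_to_peak(tail) <= OSCILLATION_THRESHOLD:
        raise NoOscillationError("no sustained oscillation in the analysis "
                                 "window")
    dt = trajectory.dt
    pk, _ = find_peaks(tail.E)
    if pk.size < 3:
        raise NoOscillationError("fewer than 3 activity peaks in the "
                                 "analysis window")
    f_interval = 1.0 / (float(np.mean(np.diff(pk))) * dt)
    # Spectral estimate on a whole number of cycles (bin-centered peak).
    seg = tail.E[pk[0]:pk[-1] + 1]
    if seg.size * dt < 2.0:
        seg = tail.E
    freqs, power = power_spectrum(seg, dt)
    f_spec = float(freqs[1:][np.argmax(power[1:])])
    if abs(f_spec - f_interval) > agreement_tol:
        raise NoOscillationError(
            f"frequency estimates disagree: periodogram {f_spec:.3f} Hz vs "
            f"inter-peak {f_interval:.3f} Hz")
    return f_interval


def _input_phase(trajectory: Trajectory, switch_time: float, f_in: float,
                 phi0: float) -> np.ndarray:
    return (2.0 * math.pi * f_in * (trajectory.t - switch_time)
            + phi0) % (2.0 * math.pi)


def final_phase_difference(trajectory: Trajectory, switch_time: float,
                           f_in: float, phi0: float, index: float,
                           window: float = STEADY_WINDOW,
                           ) -> Tuple[float, bool]:
    """Circular-mean phase lag (input minus E) over the final window.

    Only defined for complete 1:1 entrainment.  Returns the phase difference
    in [0, 2 pi) and an anti-phase flag (difference within pi/4 of pi).

    Raises
    ------
    UndefinedPhaseError
        If ``index`` does not exceed the complete-entrainment threshold.
    """
    if index <= FULL_ENTRAINMENT_THRESHOLD:
        raise UndefinedPhaseError(
            "final phase difference requires complete entrainment "
            f"(index > {FULL_ENTRAINMENT_THRESHOLD})")
    from .drive import intrinsic_phase

    t_end = trajectory.t[-1]
    tail = trajectory.window(t_end - window, t_end)
    # Both phases in the peak-anchored convention: the input sinusoid peaks
    # at sine phase pi/2, so subtracting pi/2 makes zero lag mean
    # "E peaks where the input peaks".
    phi_in = (_input_phase(tail, switch_time, f_in, phi0)
              - math.pi / 2) % (2 * math.pi)
    phi_e = intrinsic_phase(trajectory, tail.t)
    d = phi_in - phi_e
    mean = math.atan2(np.mean(np.sin(d)), np.mean(np.cos(d))) % (2 * math.pi)
    anti = abs(((mean - math.pi) + math.pi) % (2 * math.pi) - math.pi) \
        <= math.pi / 4
    return mean, anti


def evaluate_entrainment(trajectory: Trajectory, switch_time: float,
                         f_in: float, phi0: float = 0.0,
                         compute_phase: bool = False) -> EntrainmentResult:
    """Full entrainment analysis of one constant-then-sinusoidal run.

    The spectral segment is the post-convergence portion of E(t); when
    convergence is undefined the last 10 s (or the post-switch portion, if
    shorter) are used.  The convergence time is reported only when the index
    exceeds the complete-entrainment threshold.
    """
    conv, converged = convergence_time(trajectory, switch_time)
    t_end = trajectory.t[-1]
    if converged:
        seg_start = switch_time + (conv or 0.0)
    else:
        seg_start = max(switch_time, t_end - 10.0)
    if t_end - seg_start < 2.0:
        seg_start = t_end - 2.0
    seg_traj = trajectory.window(seg_start, t_end)
    seg = _integer_cycles_slice(seg_traj.E, trajectory.dt, f_in)
    if float(seg.max() - seg.min()) <= OSCILLATION_THRESHOLD:
        raise NoOscillationError("response is not oscillatory after onset")
    freqs, power = power_spectrum(seg, trajectory.dt)
    bin_width = float(freqs[1] - freqs[0])
    peaks = detect_peaks(freqs, power)
    if not peaks:
        raise NoOscillationError("no spectral peaks in the response")
    spectrum = prune_harmonics(peaks, f_in, bin_width)
    index = entrainment_index(spectrum, f_in)
    result_conv = conv if (converged
                           and index > FULL_ENTRAINMENT_THRESHOLD) else None
    phase = None
    if compute_phase and index > FULL_ENTRAINMENT_THRESHOLD:
        phase, _ = final_phase_difference(trajectory, switch_time, f_in,
                                          phi0, index)
    return EntrainmentResult(index=index, convergence_time=result_conv,
                             converged=converged, final_phase_diff=phase,
                             spectrum=spectrum)
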