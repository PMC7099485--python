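"""Entrainment metrics: spectra, harmonic pruning, convergence, phases."""

import math

import numpy as np
import pytest

from wcentrain.errors import (EmptySpectrumError, InsufficientDataError,
                              NoOscillationError, UndefinedPhaseError)
from wcentrain.metrics import (convergence_time, detect_peaks,
                               entrainment_index, evaluate_entrainment,
                               final_phase_difference, natural_frequency,
                               peak_to_peak, power_spectrum, prune_harmonics)
from wcentrain.model import Trajectory
from wcentrain.synthetic import (SyntheticTrajectorySpec,
                                 generate_synthetic_trajectory)

TWO_PI = 2 * math.pi


def make_trajectory(signal, dt=0.001, baseline=1.0):
    t = dt * np.arange(signal.size)
    states = np.column_stack([signal, 0.8 * signal, 1.2 * signal])
    return Trajectory(t=t, states=states, input=np.full(signal.size,
                                                        baseline))


class TestPowerSpectrum:
    def test_pure_tone_dominant_bin(self):
        t = 0.001 * np.arange(3000)
        freqs, power = power_spectrum(np.sin(TWO_PI * 6 * t), 0.001)
        assert abs(freqs[np.argmax(power)] - 6.0) <= freqs[1] - freqs[0]

    def test_constant_segment_has_no_power(self):
        freqs, power = power_spectrum(np.full(3000, 0.7), 0.001)
        assert power.max() < 1e-12

    def test_equal_tones_split_power_equally(self):
        # 5 and 8 Hz complete an integer number of cycles in 3 s, so the
        # periodogram is leakage-free and the two peaks match exactly
        t = 0.001 * np.arange(3000)
        sig = np.sin(TWO_PI * 5 * t) + np.sin(TWO_PI * 8 * t + 0.4)
        freqs, power = power_spectrum(sig, 0.001)
        peaks = detect_peaks(freqs, power)
        assert peaks[0][1] / peaks[1][1] == pytest.approx(1.0, abs=1e-6)

    def test_short_segment_rejected(self):
        with pytest.raises(InsufficientDataError):
            power_spectrum(np.zeros(500), 0.001)


class TestPruneHarmonics:
    BIN = 1 / 3.0

    def test_harmonic_family_collapses_to_fundamental(self):
        peaks = [(2.0, 10.0), (4.0, 5.0), (6.0, 2.0), (8.0, 1.0)]
        spec = prune_harmonics(peaks, f_in=2.0, bin_width=self.BIN)
        assert len(spec.peaks) == 1
        assert spec.peaks[0] == (2.0, 1.0)
        assert spec.f_in_index == 0

    def test_drive_frequency_exception(self):
        # the harmonic at the drive frequency survives pruning so that
        # subharmonic (1:2) locking remains visible
        peaks = [(2.0, 10.0), (4.0, 1.0)]
        spec = prune_harmonics(peaks, f_in=4.0, bin_width=self.BIN)
        assert len(spec.peaks) == 2
        assert spec.peaks[0][1] == pytest.approx(10 / 11)
        assert spec.peaks[1][1] == pytest.approx(1 / 11)

    def test_incommensurate_peaks_normalized(self):
        peaks = [(5.0, 3.0), (7.3, 3.0)]
        spec = prune_harmonics(peaks, f_in=5.0, bin_width=self.BIN)
        assert [p for _, p in spec.peaks] == pytest.approx([0.5, 0.5])

    def test_idempotent_on_random_peak_lists(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            n = rng.integers(1, 8)
            freqs = rng.uniform(1, 20, n)
            powers = np.sort(rng.uniform(0.1, 5, n))[::-1]
            peaks = list(zip(freqs.tolist(), powers.tolist()))
            f_in = float(rng.uniform(1, 20))
            once = prune_harmonics(peaks, f_in, self.BIN)
            twice = prune_harmonics(list(once.peaks), f_in, self.BIN)
            np.testing.assert_allclose(np.asarray(twice.peaks),
                                       np.asarray(once.peaks))
            assert sum(p for _, p in once.peaks) == pytest.approx(1.0,
                                                                  abs=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(EmptySpectrumError):
            prune_harmonics([], f_in=5.0, bin_width=self.BIN)


class TestEntrainmentIndex:
    def test_single_peak_full_entrainment(self):
        spec = prune_harmonics([(6.0, 4.0)], f_in=6.0, bin_width=0.25)
        assert entrainment_index(spec, 6.0) == 1.0

    def test_no_peak_near_drive(self):
        spec = prune_harmonics([(3.0, 4.0)], f_in=6.0, bin_width=0.25)
        assert entrainment_index(spec, 6.0) == 0.0

    def test_equal_split_two_tone_signal(self):
        t = 0.001 * np.arange(10000)
        f_in, g = 6.0, 4.3
        sig = np.sin(TWO_PI * f_in * t) + np.sin(TWO_PI * g * t)
        freqs, power = power_spectrum(sig, 0.001)
        spec = prune_harmonics(detect_peaks(freqs, power), f_in,
                               float(freqs[1]))
        assert entrainment_index(spec, f_in) == pytest.approx(0.5, abs=0.05)

    def test_subharmonic_regime_detectable(self):
        # response locked at f_in / 2: the index must stay below 0.5
        t = 0.001 * np.arange(10000)
        sig = np.sin(TWO_PI * 3.0 * t) + 0.4 * np.sin(TWO_PI * 6.0 * t)
        freqs, power = power_spectrum(sig, 0.001)
        spec = prune_harmonics(detect_peaks(freqs, power), 6.0,
                               float(freqs[1]))
        idx = entrainment_index(spec, 6.0)
        assert 0.0 < idx < 0.5

    def test_bounds_and_normalization_on_random_signals(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            n = rng.integers(1, 4)
            comps = tuple((float(rng.uniform(1, 30)),
                           float(rng.uniform(0.05, 0.5)),
                           float(rng.uniform(0, TWO_PI))) for _ in range(n))
            spec_t = SyntheticTrajectorySpec(components=comps, duration=8.0,
                                             noise_sigma=0.01)
            traj = generate_synthetic_trajectory(spec_t, seed=int(
                rng.integers(0, 2**31)))
            freqs, power = power_spectrum(traj.E, traj.dt)
            peaks = detect_peaks(freqs, power)
            f_in = float(rng.uniform(1, 30))
            spec = prune_harmonics(peaks, f_in, float(freqs[1]))
            idx = entrainment_index(spec, f_in)
            assert 0.0 <= idx <= 1.0
            assert sum(p for _, p in spec.peaks) == pytest.approx(1.0,
                                                                  abs=1e-9)


class TestConvergenceTime:
    def test_periodic_from_switch_is_immediate(self):
        spec = SyntheticTrajectorySpec(components=((5.0, 0.3, 0.0),),
                                       duration=20.0)
        traj = generate_synthetic_trajectory(spec, seed=0)
        ct, converged = convergence_time(traj, switch_time=10.0)
        assert converged
        assert ct <= traj.dt

    @pytest.mark.parametrize("length", [0.8, 1.3, 2.5])
    def test_planted_transient_recovered(self, length):
        spec = SyntheticTrajectorySpec(
            components=((5.0, 0.3, 0.0),), duration=20.0,
            transient_start=10.0, transient_length=length,
            transient_amplitude=0.3, transient_decay=3.0)
        traj = generate_synthetic_trajectory(spec, seed=1)
        ct, converged = convergence_time(traj, switch_time=10.0)
        assert converged
        assert ct == pytest.approx(length, abs=2 * traj.dt)

    def test_constant_trajectory_degenerate_cycle(self):
        spec = SyntheticTrajectorySpec(components=(), duration=20.0)
        traj = generate_synthetic_trajectory(spec, seed=0)
        ct, converged = convergence_time(traj, switch_time=10.0)
        assert converged and ct == 0.0

    def test_quasi_periodic_tail_flagged_unconverged(self):
        spec = SyntheticTrajectorySpec(
            components=((5.0, 0.3, 0.0), (5.0 * math.sqrt(2), 0.3, 0.1)),
            duration=20.0)
        traj = generate_synthetic_trajectory(spec, seed=0)
        ct, converged = convergence_time(traj, switch_time=10.0)
        assert not converged and ct is None


class TestNaturalFrequency:
    def test_sine_recovered_within_a_bin(self):
        spec = SyntheticTrajectorySpec(components=((4.25, 0.3, 0.0),),
                                       duration=10.0)
        traj = generate_synthetic_trajectory(spec, seed=0)
        assert natural_frequency(traj) == pytest.approx(4.25, abs=1 / 3.0)

    def test_flat_signal_rejected(self):
        spec = SyntheticTrajectorySpec(components=(), duration=10.0)
        traj = generate_synthetic_trajectory(spec, seed=0)
        with pytest.raises(NoOscillationError):
            natural_frequency(traj)

    def test_broadband_noise_rejected(self):
        rng = np.random.default_rng(2)
        traj = make_trajectory(0.5 + 0.3 * rng.standard_normal(10000))
        with pytest.raises(NoOscillationError):
            natural_frequency(traj)

    def test_example_set_frequencies(self, example_candidate):
        assert example_candidate.f_q0 == pytest.approx(6.5, abs=0.3)
        assert example_candidate.f_q1 == pytest.approx(5.5, abs=0.3)


class TestPeakToPeak:
    def test_constant_and_sine(self):
        t = 0.001 * np.arange(4000)
        traj = make_trajectory(0.5 + 0.21 * np.sin(TWO_PI * 5 * t))
        assert peak_to_peak(traj, "E") == pytest.approx(0.42, abs=1e-6)
        flat = make_trajectory(np.full(4000, 0.3))
        assert peak_to_peak(flat, "E") == 0.0

    def test_example_set_amplitude_match(self, example_candidate):
        c = example_candidate
        assert abs(c.ppE_q0 - c.ppE_q1) < 0.001
        assert c.ppIs_q0 >= c.ppE_q0 and c.ppIs_q1 >= c.ppE_q1


class TestFinalPhaseDifference:
    def phase_fixture(self, negate=False):
        f_in, t0, phi0 = 5.0, 10.0, 0.0
        t = 0.001 * np.arange(20001)
        sig = np.sin(TWO_PI * f_in * (t - t0) + phi0)
        if negate:
            sig = -sig
        return make_trajectory(0.5 + 0.3 * sig), t0, f_in, phi0

    def test_copy_of_input_in_phase(self):
        traj, t0, f_in, phi0 = self.phase_fixture()
        diff, anti = final_phase_difference(traj, t0, f_in, phi0, index=1.0)
        assert min(diff, TWO_PI - diff) < 0.05
        assert not anti

    def test_negated_input_anti_phase(self):
        traj, t0, f_in, phi0 = self.phase_fixture(negate=True)
        diff, anti = final_phase_difference(traj, t0, f_in, phi0, index=1.0)
        assert diff == pytest.approx(math.pi, abs=0.05)
        assert anti

    def test_requires_full_entrainment(self):
        traj, t0, f_in, phi0 = self.phase_fixture()
        with pytest.raises(UndefinedPhaseError):
            final_phase_difference(traj, t0, f_in, phi0, index=0.5)


class TestEvaluateEntrainment:
    def test_flat_response_rejected(self):
        spec = SyntheticTrajectorySpec(components=(), duration=20.0)
        traj = generate_synthetic_trajectory(spec, seed=0)
        with pytest.raises(NoOscillationError):
            evaluate_entrainment(traj, 10.0, 5.0)

    def test_entrained_synthetic_run(self):
        spec = SyntheticTrajectorySpec(components=((5.0, 0.3, 0.0),),
                                       duration=20.0, transient_start=10.0,
                                       transient_length=1.0,
                                       transient_amplitude=0.3,
                                       transient_decay=3.0)
        traj = generate_synthetic_trajectory(spec, seed=0)
        res = evaluate_entrainment(traj, 10.0, 5.0)
        assert res.index > 0.98
        assert res.convergence_time == pytest.approx(1.0, abs=0.01)
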