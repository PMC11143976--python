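import numpy as np
import pytest

from cmjkit.errors import NoCountermovementError, NoFlightError, NoMovementError
from cmjkit.kinematics import (
    KinematicSeries,
    detect_onset,
    detect_takeoff,
    integrate_motion,
    segment_phases,
)
from cmjkit.synthetic import JumpProfileParams, simulate_trial
from cmjkit.trial_io import ForceTrial

from conftest import analyze

G = 9.81


class TestOnset:
    def test_step_input_backtracks_to_step_edge(self):
        bw, sd = 700.0, 2.0
        force = np.full(4000, bw)
        force[2000:] -= 10 * sd
        trial = ForceTrial(force=force, sampling_rate=1000.0)
        assert detect_onset(trial, bw, sd) == 2000

    def test_pure_quiet_noise_raises(self, rng):
        trial = ForceTrial(
            force=700.0 + rng.normal(0, 2, 3000), sampling_rate=1000.0
        )
        with pytest.raises(NoMovementError):
            detect_onset(trial, 700.0, 2.0)

    def test_detected_onset_near_generator_truth(self, rng):
        # noisy trials: detection within 30 ms of the true movement start
        for seed in range(100):
            params = JumpProfileParams(noise_sd=5.0)
            trial, truth = simulate_trial(params, rng=np.random.default_rng(seed))
            bw, kin, seg = analyze(trial)
            err = abs(seg.onset_index / 1000.0 - truth["onset_time"])
            assert err < 0.030


class TestIntegration:
    def test_constant_net_acceleration_closed_form(self):
        # a = 2 m/s^2 for 0.5 s: v -> 1.0 m/s, displacement -> 0.25 m
        mass, rate = 70.0, 1000.0
        force = np.full(501, mass * (G + 2.0))
        trial = ForceTrial(force=force, sampling_rate=rate)
        kin = integrate_motion(trial, mass, 0)
        assert kin.velocity[-1] == pytest.approx(1.0, abs=1e-9)
        assert kin.displacement[-1] == pytest.approx(0.25, abs=2.0 / rate)

    def test_statics_gives_zero_velocity_and_power(self):
        trial = ForceTrial(force=np.full(1000, 70.0 * G), sampling_rate=1000.0)
        kin = integrate_motion(trial, 70.0, 0)
        np.testing.assert_allclose(kin.velocity, 0, atol=1e-12)
        np.testing.assert_allclose(kin.power, 0, atol=1e-12)

    def test_takeoff_velocity_matches_generator(self, baseline_trial):
        trial, truth = baseline_trial
        bw, kin, seg = analyze(trial)
        assert kin.velocity[seg.takeoff_index] == pytest.approx(
            truth["takeoff_velocity"], abs=1e-3
        )

    def test_refinement_error_shrinks_quadratically(self):
        # trapezoid error vs the requested take-off velocity is O(h^2):
        # halving the sampling interval shrinks it ~4x
        errs = {}
        for rate in (500.0, 1000.0, 2000.0):
            p = JumpProfileParams(noise_sd=0.0, sampling_rate=rate)
            _, truth = simulate_trial(p)
            errs[rate] = abs(truth["takeoff_velocity"] - p.takeoff_velocity)
        assert errs[1000.0] < 0.5 * errs[500.0]
        assert errs[2000.0] < 0.5 * errs[1000.0]


class TestTakeoff:
    def test_detected_takeoff_near_flight_start(self, baseline_trial):
        trial, truth = baseline_trial
        bw, kin, seg = analyze(trial)
        t_true = truth["onset_time"] + truth["ecc_duration"] + truth["con_duration"]
        assert abs(seg.takeoff_index / 1000.0 - t_true) < 0.005

    def test_truncated_trial_raises(self, baseline_trial):
        trial, _ = baseline_trial
        cut = ForceTrial(force=trial.force[:1900], sampling_rate=1000.0)
        with pytest.raises(NoFlightError):
            detect_takeoff(cut, 0)

    def test_threshold_sensitivity_small_on_clean_data(self, baseline_trial):
        trial, _ = baseline_trial
        t10 = detect_takeoff(trial, 0, threshold_N=10.0)
        t20 = detect_takeoff(trial, 0, threshold_N=20.0)
        assert abs(t10 - t20) <= 2  # <= 2 ms at 1 kHz


class TestSegmentation:
    def test_analytic_sine_zero_crossing(self):
        # v(t) = -sin(2 pi t) on [0, 1]: minimum at 0.25 s, upward crossing 0.5 s
        rate = 1000.0
        t = np.arange(0, 1001) / rate
        v = -np.sin(2 * np.pi * t)
        kin = KinematicSeries(
            net_acceleration=np.gradient(v, t),
            velocity=v,
            displacement=np.zeros_like(v),
            power=np.zeros_like(v),
            sampling_rate=rate,
            onset_index=0,
        )
        seg = segment_phases(kin, 0, 1000)
        assert seg.min_velocity_index == 250
        assert seg.end_of_braking_index == 500

    def test_monotone_positive_velocity_raises(self):
        rate = 1000.0
        v = np.linspace(0, 2, 500)
        kin = KinematicSeries(
            net_acceleration=np.zeros(500),
            velocity=v,
            displacement=np.zeros(500),
            power=np.zeros(500),
            sampling_rate=rate,
            onset_index=0,
        )
        with pytest.raises(NoCountermovementError):
            segment_phases(kin, 0, 499)

    def test_phase_durations_recover_generating_values(self, baseline_trial):
        trial, truth = baseline_trial
        bw, kin, seg = analyze(trial)
        rate = trial.sampling_rate
        assert seg.eccentric_duration(rate) == pytest.approx(
            truth["ecc_duration"], abs=2 / rate
        )
        assert seg.concentric_duration(rate) == pytest.approx(
            truth["con_duration"], abs=2 / rate
        )


class TestImpulseMomentum:
    def test_net_impulse_identities(self, baseline_trial):
        trial, _ = baseline_trial
        bw, kin, seg = analyze(trial)
        dt = 1.0 / trial.sampling_rate
        a = kin.net_acceleration
        ecc = np.trapezoid(
            a[seg.onset_index : seg.end_of_braking_index + 1], dx=dt
        )
        # velocity starts and ends the eccentric phase near zero (the end
        # is snapped to the first non-negative sample)
        assert abs(ecc) < 0.02
        con = np.trapezoid(
            a[seg.end_of_braking_index : seg.takeoff_index + 1], dx=dt
        )
        assert con == pytest.approx(
            kin.velocity[seg.takeoff_index] - kin.velocity[seg.end_of_braking_index],
            abs=1e-3,
        )
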