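import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cmjkit.errors import InfeasibleProfileError
from cmjkit.rm_stats import rm_anova
from cmjkit.synthetic import (
    CohortSpec,
    FatigueEffect,
    JumpProfileParams,
    _fatigue_force_weight,
    feasible_downward_velocity_limit,
    simulate_cohort,
    simulate_trial,
    simulate_velocity_profile,
    velocity_to_force,
)

from conftest import analyze

G = 9.81


class TestVelocityProfile:
    def test_endpoint_constraints_imposed_by_construction(self):
        p = JumpProfileParams(
            peak_downward_velocity=1.35, takeoff_velocity=3.08, noise_sd=0.0
        )
        kin = simulate_velocity_profile(p)
        v = kin.velocity
        assert v[0] == pytest.approx(0.0, abs=1e-12)
        assert v.min() == pytest.approx(-1.35, abs=1e-6)
        assert v[-1] == pytest.approx(3.08, abs=1e-6)
        i_min = np.argmin(v)
        after = v[i_min:]
        crossings = np.sum((after[:-1] < 0) & (after[1:] >= 0))
        assert crossings == 1

    def test_phase_durations_match_parameters(self):
        p = JumpProfileParams(ecc_duration=0.35, con_duration=0.25, noise_sd=0.0)
        kin = simulate_velocity_profile(p)
        v = kin.velocity
        i_min = np.argmin(v)
        eob = i_min + np.flatnonzero(v[i_min:] >= 0)[0]
        rate = p.sampling_rate
        assert eob / rate == pytest.approx(0.35, abs=1.5 / rate)
        assert (v.size - 1 - eob) / rate == pytest.approx(0.25, abs=1.5 / rate)

    def test_doubling_rate_leaves_velocity_unchanged_at_shared_points(self):
        p1 = JumpProfileParams(noise_sd=0.0, sampling_rate=1000.0)
        p2 = JumpProfileParams(noise_sd=0.0, sampling_rate=2000.0)
        v1 = simulate_velocity_profile(p1).velocity
        v2 = simulate_velocity_profile(p2).velocity
        np.testing.assert_allclose(v1, v2[::2], atol=1e-9)

    def test_too_violent_profile_rejected(self):
        # descent faster than free fall allows in the available time
        p = JumpProfileParams(
            ecc_duration=0.20, peak_downward_velocity=2.5, noise_sd=0.0
        )
        with pytest.raises(InfeasibleProfileError):
            simulate_velocity_profile(p)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        te=st.floats(0.28, 0.45),
        tc=st.floats(0.20, 0.33),
        vto=st.floats(2.4, 3.4),
        vmin_frac=st.floats(0.5, 1.0),
    )
    def test_force_nonnegative_and_impulse_consistent(self, te, tc, vto, vmin_frac):
        # across the feasible parameter box: F >= 0 everywhere and the
        # net impulse from onset to take-off equals the take-off velocity
        vmin = vmin_frac * feasible_downward_velocity_limit(te)
        p = JumpProfileParams(
            ecc_duration=te,
            con_duration=tc,
            takeoff_velocity=vto,
            peak_downward_velocity=vmin,
            noise_sd=0.0,
            sampling_rate=4000.0,
        )
        kin = simulate_velocity_profile(p)
        assert np.all(kin.net_acceleration + G >= -1e-9)
        dt = 1.0 / p.sampling_rate
        net_impulse = np.trapezoid(kin.net_acceleration, dx=dt)
        assert net_impulse == pytest.approx(vto, abs=1e-4)


class TestVelocityToForce:
    def test_statics_constant_body_weight(self):
        from cmjkit.kinematics import KinematicSeries

        n, mass = 1000, 70.0
        kin = KinematicSeries(
            net_acceleration=np.zeros(n),
            velocity=np.zeros(n),
            displacement=np.zeros(n),
            power=np.zeros(n),
            sampling_rate=1000.0,
            onset_index=0,
        )
        trial, truth = velocity_to_force(kin, mass, 0.5, 0.0, landing=False)
        np.testing.assert_allclose(trial.force, mass * G, atol=1e-9)

    def test_round_trip_recovers_takeoff_velocity(self, baseline_trial):
        trial, truth = baseline_trial
        bw, kin, seg = analyze(trial)
        assert kin.velocity[seg.takeoff_index] == pytest.approx(
            3.08, abs=1e-3
        )

    def test_flight_apex_matches_ballistics(self, baseline_params):
        # apex of the flight phase = v_to^2 / (2g), to within 0.1 cm
        trial, truth = simulate_trial(baseline_params)
        bw, kin, seg = analyze(trial)
        flight = kin.displacement[seg.takeoff_index :]
        apex_rel = flight.max() - flight[0]
        expected = truth["takeoff_velocity"] ** 2 / (2 * G)
        assert apex_rel == pytest.approx(expected, abs=0.001)

    def test_force_never_negative_with_noise(self, rng):
        trial, _ = simulate_trial(JumpProfileParams(noise_sd=8.0), rng=rng)
        assert trial.force.min() >= 0.0


class TestFatigueEffect:
    def test_identity_effect_changes_nothing(self, baseline_params):
        t0, _ = simulate_trial(baseline_params)
        t1, _ = simulate_trial(baseline_params, FatigueEffect())
        np.testing.assert_array_equal(t0.force, t1.force)

    def test_force_deficit_localized_to_window(self, baseline_params):
        # mean force reduction inside the 50-75% window matches the
        # analytic mean of the tapered deficit profile
        reduction = 0.15
        eff = FatigueEffect(con_force_reduction=reduction)
        t0, _ = simulate_trial(baseline_params)
        t1, _ = simulate_trial(baseline_params, eff)
        n = min(t0.n_samples, t1.n_samples)
        ratio = np.divide(
            t1.force[:n], t0.force[:n], out=np.ones(n), where=t0.force[:n] > 1
        )
        te, tc, rate = 0.35, 0.25, 1000.0
        move0 = int(1.5 * rate)
        n_move = int(round((te + tc) * rate)) + 1
        w = _fatigue_force_weight(n_move, te, tc, rate, (50.0, 75.0))
        observed = 1.0 - ratio[move0 : move0 + n_move]
        np.testing.assert_allclose(observed, reduction * w, atol=1e-9)
        # outside the window the trace is untouched
        assert np.all(observed[w == 0] == 0)

    def test_deficit_reduces_takeoff_velocity(self, baseline_params):
        _, truth0 = simulate_trial(baseline_params)
        _, truth1 = simulate_trial(
            baseline_params, FatigueEffect(con_force_reduction=0.15)
        )
        assert truth1["takeoff_velocity"] < truth0["takeoff_velocity"]


class TestCohort:
    def test_fixed_seed_gives_identical_traces(self):
        spec = CohortSpec(n_participants=3, trials_per_session=2, seed=99)
        t1, g1 = simulate_cohort(spec)
        t2, g2 = simulate_cohort(spec)
        assert len(t1) == len(t2) == 3 * 5 * 2
        for a, b in zip(t1, t2):
            np.testing.assert_array_equal(a.force, b.force)
        assert g1.equals(g2)

    def test_null_cohort_anova_rejects_at_nominal_rate(self):
        # identity effects for every condition: JH RM-ANOVA should reject
        # at ~ the nominal 5% level
        null = {c: FatigueEffect() for c in ("3min", "10min", "1hr", "24hr")}
        rejections = 0
        reps = 150
        for seed in range(reps):
            spec = CohortSpec(
                n_participants=8, trials_per_session=1, seed=10_000 + seed
            )
            _, truth = simulate_cohort(spec, effects=null)
            wide = truth.pivot_table(
                index="participant", columns="condition", values="jump_height_cm"
            )
            res = rm_anova(wide.to_numpy())
            rejections += res.p_value < 0.05
        # binomial 95% band around 0.05 for 150 replicates
        assert 0.01 <= rejections / reps <= 0.09

    def test_ground_truth_matches_pipeline_estimates(self):
        spec = CohortSpec(n_participants=3, trials_per_session=1, seed=5)
        trials, truth = simulate_cohort(
            spec,
            baseline=JumpProfileParams(noise_sd=0.0),
        )
        for trial, row in zip(trials, truth.itertuples(index=False)):
            bw, kin, seg = analyze(trial)
            v_to = kin.velocity[seg.takeoff_index]
            assert v_to == pytest.approx(row.takeoff_velocity, abs=2e-3)
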