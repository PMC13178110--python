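"""Simulator unit tests: pharmacodynamics, sensor-pool kinetics, frame
rendering and cohort assembly, each checked against an independent oracle
(closed forms, a scipy ODE integrator, or direct construction)."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import solve_ivp

from photofret import (
    DrugEffectProfile,
    SensorKineticsParams,
    SessionSchedule,
    SimulatedCohortSpec,
    TreatmentArm,
    activity_trace,
    magnitude_for_delta_fret,
    render_session,
    sensor_pool_trace,
    simulate_cohort,
)


# ---------------------------------------------------------------------------
# drug pharmacodynamics
# ---------------------------------------------------------------------------

class TestActivityTrace:
    def test_vehicle_is_constant(self):
        prof = DrugEffectProfile("vehicle")
        t = np.linspace(0, 3, 50)
        assert np.all(activity_trace(prof, 1.0, t) == 1.0)

    def test_inhibitor_halves_activity_at_peak(self):
        prof = DrugEffectProfile("inhibitor", magnitude=0.5, k_on=6.0, k_off=0.5)
        t_peak = math.log(6.0 / 0.5) / (6.0 - 0.5)
        a = activity_trace(prof, 2.0, np.array([t_peak]))
        assert a[0] == pytest.approx(1.0, rel=1e-12)  # 0.5 * a0

    def test_activator_matches_effect_compartment_ode(self):
        # independent oracle: the onset/washout curve is the (normalised)
        # second compartment of an absorption -> effect -> elimination chain
        k_on, k_off = 6.0, 0.5
        prof = DrugEffectProfile("activator", magnitude=1.0, k_on=k_on, k_off=k_off)

        def rhs(t, y):
            return [-k_on * y[0], k_on * y[0] - k_off * y[1]]

        t_dense = np.linspace(0, 6, 4001)
        sol = solve_ivp(rhs, (0, 6), [1.0, 0.0], t_eval=t_dense, rtol=1e-11, atol=1e-13)
        effect = sol.y[1] / sol.y[1].max()
        for t_query in (0.25, 1.0, 2.5):
            expected = 1.0 + np.interp(t_query, t_dense, effect)
            got = activity_trace(prof, 1.0, np.array([t_query]))[0]
            assert got == pytest.approx(expected, rel=1e-5)

    def test_activator_value_at_one_hour_frozen(self):
        # direct evaluation of the unit-peak Bateman expression at t=1 h,
        # k_on=6/h, k_off=0.5/h (value frozen from the closed form)
        prof = DrugEffectProfile("activator", magnitude=1.0, k_on=6.0, k_off=0.5)
        t_peak = math.log(12.0) / 5.5
        peak = math.exp(-0.5 * t_peak) - math.exp(-6.0 * t_peak)
        expected = 1.0 + (math.exp(-0.5) - math.exp(-6.0)) / peak
        assert activity_trace(prof, 1.0, np.array([1.0]))[0] == pytest.approx(
            expected, rel=1e-12
        )
        assert expected == pytest.approx(1.82598, abs=5e-5)

    def test_full_inhibition_rejected(self):
        with pytest.raises(ValueError, match="magnitude"):
            DrugEffectProfile("inhibitor", magnitude=1.0)

    def test_vehicle_with_magnitude_rejected(self):
        with pytest.raises(ValueError):
            DrugEffectProfile("vehicle", magnitude=0.2)

    def test_sustained_effect_has_unit_asymptote(self):
        prof = DrugEffectProfile("inhibitor", magnitude=0.5, k_on=50.0, k_off=0.0)
        b = prof.bateman(np.array([1.0, 3.0]))
        assert np.all(b > 0.999) and np.all(b <= 1.0)


# ---------------------------------------------------------------------------
# sensor-pool kinetics
# ---------------------------------------------------------------------------

class TestSensorPool:
    def test_constant_activity_stays_at_steady_state(self, clean_params):
        t = np.linspace(0, 3, 100)
        s = sensor_pool_trace(clean_params, lambda tt: np.full_like(tt, clean_params.a0), t)
        assert np.allclose(s, clean_params.steady_state, rtol=1e-9)

    def test_halved_activity_doubles_pool_without_turnover(self):
        params = SensorKineticsParams(k_deg=0.0, k_cl=3.0, a0=1.0, noise_sd=0.0)
        t = np.linspace(0, 20, 400)  # t >> 1/(k_cl * a)
        s = sensor_pool_trace(params, lambda tt: np.full_like(tt, 0.5), t)
        assert s[-1] / params.steady_state == pytest.approx(2.0, rel=1e-4)

    @pytest.mark.parametrize("f", [0.1, 0.25, 0.5])
    def test_sustained_inhibition_master_oracle(self, f):
        # closed form: with k_deg=0 the steady-state pool scales as 1/(1-f),
        # i.e. a fractional inhibition f gives dFRET_ss = 100 f/(1-f)
        params = SensorKineticsParams(k_deg=0.0, noise_sd=0.0, bleach_rate=0.0)
        t = np.linspace(0, 30, 600)
        s = sensor_pool_trace(params, lambda tt: np.full_like(tt, params.a0 * (1 - f)), t)
        delta = 100.0 * (s[-1] - s[0]) / s[0]
        assert delta == pytest.approx(100.0 * f / (1.0 - f), rel=1e-4)

    def test_rk4_matches_reference_integrator_for_time_varying_activity(self, clean_params):
        prof = DrugEffectProfile("inhibitor", magnitude=0.6, k_on=6.0, k_off=0.5)
        a_fn = lambda tt: activity_trace(prof, clean_params.a0, np.atleast_1d(tt))  # noqa: E731
        t = np.linspace(0, 3, 31)
        s = sensor_pool_trace(clean_params, a_fn, t)

        def rhs(tt, y):
            return clean_params.k_syn - (
                clean_params.k_deg + clean_params.k_cl * float(a_fn(np.array([tt]))[0])
            ) * y

        ref = solve_ivp(rhs, (0, 3), [clean_params.steady_state], t_eval=t,
                        rtol=1e-10, atol=1e-12)
        assert np.allclose(s, ref.y[0], rtol=1e-3)  # spec'd solver error budget: <0.1%

    def test_no_steady_state_rejected(self):
        with pytest.raises(ValueError, match="steady state"):
            SensorKineticsParams(k_deg=0.0, k_cl=0.0)

    def test_magnitude_for_delta_fret_inverts_steady_state_map(self, clean_params):
        f = magnitude_for_delta_fret(clean_params, 30.0)
        tot0 = clean_params.k_deg + clean_params.k_cl * clean_params.a0
        ratio = tot0 / (clean_params.k_deg + clean_params.k_cl * clean_params.a0 * (1 - f))
        assert 100.0 * (ratio - 1.0) == pytest.approx(30.0, rel=1e-12)


# ---------------------------------------------------------------------------
# frame rendering
# ---------------------------------------------------------------------------

class TestRenderSession:
    def test_noiseless_frames_are_exact(self, clean_params, mini_schedule):
        frames = render_session(clean_params, 30.0 / clean_params.gain, mini_schedule, seed=0)
        on = frames[frames.LedState == 1]["Region0"]
        off = frames[frames.LedState == 0]["Region0"]
        assert np.allclose(on, 30.0 + clean_params.ambient)
        assert np.allclose(off, clean_params.ambient)

    def test_frame_counts_at_default_rate(self, clean_params):
        schedule = SessionSchedule()
        frames = render_session(clean_params, 1.0, schedule, seed=0)
        in_window = frames[frames.Timestamp >= schedule.off_lead_s]
        assert len(in_window) == 2460  # 41 fps x 60 s
        assert int(in_window.LedState.sum()) == 1230  # strict alternation
        assert int(frames.LedState[frames.Timestamp < 60.0].sum()) == 0  # dark lead-in
        assert list(frames.FrameCounter) == list(range(len(frames)))

    def test_same_seed_reproduces_stream(self, default_params, mini_schedule):
        a = render_session(default_params, 25.0, mini_schedule, seed=7)
        b = render_session(default_params, 25.0, mini_schedule, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_bleaching_decays_gain_with_cumulative_on_time(self, mini_schedule):
        params = SensorKineticsParams(noise_sd=0.0, bleach_rate=0.01)
        frames = render_session(params, 30.0, mini_schedule, seed=0)
        on = frames[frames.LedState == 1]
        fluor = (on["Region0"] - params.ambient).to_numpy()
        # k-th on-frame has accrued k/fps seconds of exposure
        k = np.arange(len(on))
        expected = 30.0 * params.gain * np.exp(-params.bleach_rate * k / params.fps)
        assert np.allclose(fluor, expected, rtol=1e-12)
        assert fluor[-1] < fluor[0]

    def test_slow_common_mode_artifact_cancels_in_the_mean(self, clean_params, mini_schedule):
        artifact = lambda t: 4.0 * np.sin(2 * np.pi * t / 5.0)  # noqa: E731
        base = render_session(clean_params, 30.0, mini_schedule, seed=0)
        bumped = render_session(clean_params, 30.0, mini_schedule,
                                motion_artifact=artifact, seed=0)
        win = base.Timestamp >= mini_schedule.off_lead_s
        for frames in (base, bumped):
            frames = frames[win]
        diff_on = (bumped[win & (base.LedState == 1)].Region0.mean()
                   - base[win & (base.LedState == 1)].Region0.mean())
        diff_off = (bumped[win & (base.LedState == 0)].Region0.mean()
                    - base[win & (base.LedState == 0)].Region0.mean())
        # the FRET statistic shifts by the difference of the artifact means
        assert abs(diff_on - diff_off) < 0.05


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

class TestSimulateCohort:
    def test_latin_square_orders(self, mini_schedule):
        arms = tuple(
            TreatmentArm(lbl, DrugEffectProfile("vehicle")) for lbl in "abcd"
        )
        spec = SimulatedCohortSpec(n_animals=4, treatments=arms, jitter_cv=0.0,
                                   seed=0, latin_square=True)
        sim = simulate_cohort(spec, SensorKineticsParams(noise_sd=0.0), mini_schedule)
        sessions = pd.DataFrame(sim.manifest["sessions"])
        order = sessions.drop_duplicates(["animal_id", "treatment"])
        for day in range(1, 5):
            treatments_on_day = order[order.day == day]["treatment"]
            assert sorted(treatments_on_day) == list("abcd")  # each exactly once per position

    def test_manifest_covers_every_cell(self, small_cohort_spec, mini_schedule, default_params):
        sim = simulate_cohort(small_cohort_spec, default_params, mini_schedule)
        sessions = pd.DataFrame(sim.manifest["sessions"])
        assert len(sessions) == 3 * 2 * 4  # animals x treatments x hours
        assert set(sessions.hour) == {0.0, 1.0, 2.0, 3.0}
        assert len(sim.recordings) == len(sessions)
        assert all(f in sim.recordings for f in sessions.file)

    def test_fixed_seed_reproduces_cohort(self, small_cohort_spec, mini_schedule, default_params):
        a = simulate_cohort(small_cohort_spec, default_params, mini_schedule)
        b = simulate_cohort(small_cohort_spec, default_params, mini_schedule)
        assert a.manifest == b.manifest
        for key in a.recordings:
            pd.testing.assert_frame_equal(a.recordings[key], b.recordings[key])

    def test_jitter_preserves_mean_scale(self, mini_schedule, vehicle_arm):
        spec = SimulatedCohortSpec(n_animals=200, treatments=(vehicle_arm,),
                                   jitter_cv=0.3, seed=3)
        sim = simulate_cohort(spec, SensorKineticsParams(noise_sd=0.0), mini_schedule)
        # lognormal multipliers are unit-mean: cohort-average k_syn near nominal
        assert sim.animal_params.k_syn.mean() == pytest.approx(100.0, rel=0.1)
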