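"""Compartmental simulator: hazards, flows, conservation laws, calibration."""

import numpy as np
import pytest

from dmscore.model import (
    ALL_PROFILES,
    CompartmentState,
    InvariantViolation,
    ModelParams,
    PrevalenceTarget,
    RiskProfile,
    UndefinedPrevalence,
    band_label,
    bands_in_range,
    calibrate,
    incidence_hazard,
    prevalence,
    simulate,
    step,
)


class TestRiskProfile:
    def test_eight_distinct_profiles_with_stable_codes(self):
        codes = {p.code for p in ALL_PROFILES}
        assert codes == set(range(8))
        for p in ALL_PROFILES:
            assert RiskProfile.from_code(p.code) == p
        assert len({hash(p) for p in ALL_PROFILES}) == 8

    def test_band_labels_and_frame(self):
        assert band_label(3) == "15-19"
        assert band_label(15) == "75-79"
        assert bands_in_range(15, 79) == list(range(3, 16))


class TestIncidenceHazard:
    def test_no_factors_gives_baseline_exactly(self):
        p = ModelParams.from_scalars(baseline_incidence=0.017, rr=[2, 3, 4])
        assert incidence_hazard(p, 1, 7, RiskProfile()) == 0.017

    def test_multiplicative_combination(self):
        p = ModelParams.from_scalars(baseline_incidence=0.01, rr=[2, 1.5, 1.3])
        h = incidence_hazard(p, 0, 5, RiskProfile(True, True, True))
        assert h == pytest.approx(0.039, rel=1e-12)

    def test_neutral_relative_risks_ignore_profile(self):
        p = ModelParams.from_scalars(baseline_incidence=0.02, rr=1.0)
        hazards = {incidence_hazard(p, 0, 4, prof) for prof in ALL_PROFILES}
        assert hazards == {0.02}

    def test_monotone_in_added_factors_when_rr_ge_one(self):
        p = ModelParams.from_scalars(baseline_incidence=0.01,
                                     rr=[1.8, 1.0, 1.4])
        for prof in ALL_PROFILES:
            h = incidence_hazard(p, 0, 8, prof)
            for f, flag in enumerate(prof):
                if not flag:
                    richer = RiskProfile.from_code(prof.code | 1 << f)
                    assert incidence_hazard(p, 0, 8, richer) >= h

    def test_bad_indices_raise(self):
        p = ModelParams.from_scalars(baseline_incidence=0.01)
        with pytest.raises(IndexError):
            incidence_hazard(p, 2, 0, RiskProfile())
        with pytest.raises(IndexError):
            incidence_hazard(p, 0, 20, RiskProfile())


class TestStep:
    def test_null_dynamics_leave_state_unchanged(self, adult_state, null_params):
        after = step(adult_state, null_params, 0.25)
        assert after.time == 0.25
        np.testing.assert_array_equal(after.occupancy, adult_state.occupancy)

    def test_closed_population_conserves_total(self, adult_state):
        # entry and mortality zero, but aging, factor and disease flows active
        params = ModelParams.from_scalars(
            onset=0.05, reversal=0.02, baseline_incidence=0.03,
            rr=[2.0, 1.5, 1.3],
        )
        state = adult_state
        for _ in range(100):
            state = step(state, params, 0.1)
        assert state.total == pytest.approx(adult_state.total, rel=1e-9)
        assert (state.occupancy >= 0).all()

    def test_diabetic_mass_nondecreasing_in_closed_cohort(self, adult_state):
        params = ModelParams.from_scalars(
            baseline_incidence=0.05, onset=0.1, rr=[2, 1, 1], aging_rate=0.2
        )
        state = adult_state
        prev = 0.0
        for _ in range(50):
            state = step(state, params, 0.1)
            dia = state.occupancy[..., 1].sum()
            assert dia >= prev - 1e-12
            prev = dia

    @pytest.mark.parametrize("dt", [0.05, 0.025, 0.0125])
    def test_single_cohort_matches_exponential_survival(self, dt):
        # one compartment, constant hazard, no competing flows
        lam, horizon = 0.3, 5.0
        state = CompartmentState.zeros()
        state.occupancy[0, 10, 0, 0] = 1.0
        params = ModelParams.from_scalars(baseline_incidence=lam,
                                          aging_rate=0.0)
        final = simulate(state, params, horizon, dt)[-1]
        frac = final.occupancy[0, 10, 0, 1]
        exact = 1 - np.exp(-lam * horizon)
        # forward Euler is first order: error bounded by ~ lam^2 * t * dt / 2
        assert abs(frac - exact) < lam**2 * horizon * dt

    def test_discretization_error_shrinks_as_dt_halves(self):
        lam, horizon = 0.4, 4.0
        state = CompartmentState.zeros()
        state.occupancy[1, 8, 0, 0] = 1.0
        params = ModelParams.from_scalars(baseline_incidence=lam,
                                          aging_rate=0.0)
        exact = 1 - np.exp(-lam * horizon)
        errors = []
        for dt in (0.2, 0.1, 0.05):
            frac = simulate(state, params, horizon, dt)[-1].occupancy[1, 8, 0, 1]
            errors.append(abs(frac - exact))
        assert errors[0] > errors[1] > errors[2]
        assert errors[1] / errors[0] == pytest.approx(0.5, abs=0.1)

    def test_oversized_dt_rejected(self, adult_state):
        params = ModelParams.from_scalars(baseline_incidence=3.0,
                                          aging_rate=0.0)
        with pytest.raises(InvariantViolation):
            step(adult_state, params, 0.5)

    def test_entry_feeds_youngest_band(self, null_params):
        params = ModelParams.from_scalars(entry_rate=100.0, aging_rate=0.0)
        state = step(CompartmentState.zeros(), params, 0.25)
        assert state.occupancy[0, 0, 0, 0] == pytest.approx(25.0)
        assert state.total == pytest.approx(50.0)


class TestSimulate:
    def test_minimal_horizon_yields_two_states(self, adult_state, null_params):
        traj = simulate(adult_state, null_params, 0.1, dt=0.1)
        assert len(traj) == 2
        assert traj[0].time == 0.0 and traj[1].time == pytest.approx(0.1)

    def test_scale_equivariance(self, adult_state):
        params = ModelParams.from_scalars(
            entry_rate=50.0, mortality=0.01, onset=0.04,
            baseline_incidence=0.02, rr=[2, 1.5, 1.3],
        )
        doubled_params = params.copy()
        doubled_params.entry_rate = params.entry_rate * 2
        doubled_state = CompartmentState(0.0, adult_state.occupancy * 2)
        a = simulate(adult_state, params, 5.0, 0.1)[-1]
        b = simulate(doubled_state, doubled_params, 5.0, 0.1)[-1]
        np.testing.assert_allclose(b.occupancy, 2 * a.occupancy, rtol=1e-12)

    def test_trajectory_convergence_under_dt_refinement(self, adult_state):
        params = ModelParams.from_scalars(
            onset=0.05, baseline_incidence=0.03, rr=[2, 1.5, 1.3]
        )
        p_coarse = prevalence(simulate(adult_state, params, 30.0, 0.2)[-1],
                              "diabetes")
        p_fine = prevalence(simulate(adult_state, params, 30.0, 0.1)[-1],
                            "diabetes")
        assert abs(p_coarse - p_fine) < 5e-3

    def test_long_format_round_trip(self, adult_state):
        frame = adult_state.to_frame()
        back = CompartmentState.from_frame(frame)
        assert back.time == adult_state.time
        np.testing.assert_array_equal(back.occupancy, adult_state.occupancy)


class TestPrevalence:
    def test_all_diabetic_is_one(self):
        state = CompartmentState.zeros()
        state.occupancy[:, 5, 0, 1] = 10.0
        assert prevalence(state, "diabetes") == 1.0

    def test_single_stratum_is_zero_or_one(self):
        state = CompartmentState.zeros()
        state.occupancy[1, 6, 3, 0] = 7.0
        assert prevalence(state, "diabetes") == 0.0
        assert prevalence(state, "obesity") == 1.0  # profile 3 = obese+smoker

    def test_hand_built_four_compartments(self):
        state = CompartmentState.zeros()
        state.occupancy[0, 5, 0, 1] = 10.0
        state.occupancy[0, 6, 0, 1] = 30.0
        state.occupancy[0, 7, 0, 0] = 20.0
        state.occupancy[0, 8, 0, 0] = 40.0
        assert prevalence(state, "diabetes") == pytest.approx(0.40)

    def test_filters(self, adult_state):
        adult_state.occupancy[1, 10, 1, 1] = 500.0  # obese diabetic men 50-54
        p_men = prevalence(adult_state, "diabetes", sex="male")
        p_women = prevalence(adult_state, "diabetes", sex="female")
        assert p_men > 0 and p_women == 0.0
        assert prevalence(adult_state, "obesity", age_range=(50, 54),
                          sex="male") == pytest.approx(500 / 1500)

    def test_empty_filter_raises(self):
        with pytest.raises(UndefinedPrevalence):
            prevalence(CompartmentState.zeros(), "diabetes")


class TestCalibrate:
    def _targets_from(self, state, params, years, dt=0.1):
        traj = simulate(state, params, max(years), dt)
        times = np.array([s.time for s in traj])
        out = []
        for y, q in zip(years, ("diabetes", "obesity", "inactivity")):
            s = traj[int(np.argmin(np.abs(times - y)))]
            out.append(PrevalenceTarget(y, q, prevalence(s, q)))
        return out

    def test_zero_free_parameters_returns_start(self, adult_state):
        params = ModelParams.from_scalars(baseline_incidence=0.02)
        targets = [PrevalenceTarget(5.0, "diabetes", 0.1)]
        res = calibrate(adult_state, params, targets, free={})
        np.testing.assert_array_equal(res.params.baseline_incidence,
                                      params.baseline_incidence)
        assert res.loss >= 0

    def test_parameter_recovery_within_one_percent(self, adult_state):
        true = ModelParams.from_scalars(
            baseline_incidence=0.02, rr=[2.0, 1.5, 1.3]
        )
        true.onset[0] = 0.05  # obesity onset
        true.onset[2] = 0.08  # inactivity onset
        targets = self._targets_from(adult_state, true, (10.0, 10.0, 10.0))
        start = ModelParams.from_scalars(
            baseline_incidence=0.05, rr=[2.0, 1.5, 1.3]
        )
        start.onset[0] = 0.02
        start.onset[2] = 0.03
        res = calibrate(
            adult_state, start, targets,
            free={"baseline_incidence": (1e-4, 0.5), "onset[0]": (1e-4, 0.5),
                  "onset[2]": (1e-4, 0.5)},
        )
        assert res.free["baseline_incidence"] == pytest.approx(0.02, rel=0.01)
        assert res.free["onset[0]"] == pytest.approx(0.05, rel=0.01)
        assert res.free["onset[2]"] == pytest.approx(0.08, rel=0.01)

    def test_conflicting_targets_land_between(self, adult_state):
        targets = [
            PrevalenceTarget(5.0, "diabetes", 0.1),
            PrevalenceTarget(5.0, "diabetes", 0.3),
        ]
        start = ModelParams.from_scalars(baseline_incidence=0.01)
        res = calibrate(adult_state, start, targets,
                        free={"baseline_incidence": (1e-5, 1.0)})
        fitted = prevalence(
            simulate(adult_state, res.params, 5.0, 0.1)[-1], "diabetes"
        )
        assert 0.1 < fitted < 0.3

    def test_overparameterised_spec_warns_not_errors(self, adult_state):
        targets = [PrevalenceTarget(2.0, "diabetes", 0.05)]
        start = ModelParams.from_scalars(baseline_incidence=0.01)
        with pytest.warns(UserWarning, match="unidentifiable"):
            calibrate(adult_state, start, targets,
                      free={"baseline_incidence": (1e-5, 1.0),
                            "rr[0]": (0.5, 5.0)})
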