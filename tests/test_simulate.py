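"""Generating model: superposed oral PK, excretion balance, hair deposition."""

import dataclasses

import numpy as np
import pytest
from scipy.integrate import quad, solve_ivp

import hairscreen as hs
from hairscreen.simulate import calibration_levels


class TestPlasmaConcentration:
    def test_zero_before_first_dose(self, short_params):
        assert hs.plasma_concentration(short_params, 2.0, [24.0], 10.0) == 0.0

    def test_matches_numerically_integrated_ode(self):
        """Single oral dose vs the two-ODE absorption/elimination system."""
        p = hs.PKParameters(ka=1.0, ke=0.1, v_over_f=1.0, bsv_sigma=0.0)

        def rhs(_t, y):
            gut, central = y
            return [-p.ka * gut, p.ka * gut - p.ke * central]

        # D/(V/F) = 1 mg/kg / 1 L/kg -> 1000 ng/mL equivalent
        sol = solve_ivp(rhs, (0, 2.0), [1000.0, 0.0], rtol=1e-10, atol=1e-12)
        expected = sol.y[1][-1]
        got = hs.plasma_concentration(p, 1.0, [0.0], 2.0)
        assert got == pytest.approx(expected, rel=1e-3)

    def test_day7_profile_positive_and_unimodal(self, short_params, design):
        grid = np.array(design.plasma_times_day7[1:])  # (0, 12] post-dose
        conc = hs.plasma_concentration(
            short_params, 2.0, design.dose_times_h(), 168.0 + grid
        )
        assert np.all(conc > 0)
        diffs = np.sign(np.diff(conc))
        # rises then falls: at most one sign change
        assert np.sum(np.diff(diffs) != 0) <= 1

    def test_equal_rates_rejected(self):
        p = hs.PKParameters(ka=0.5, ke=0.499999999, v_over_f=4.0)
        with pytest.raises(ValueError, match="degenerate"):
            hs.plasma_concentration(p, 1.0, [0.0], 1.0)

    def test_dose_proportionality(self, short_params, design):
        """Noise-free curves scale exactly linearly across the dose groups."""
        t = 168.0 + np.array(design.plasma_times_day7[1:])
        c1 = hs.plasma_concentration(short_params, 1.0, design.dose_times_h(), t)
        c4 = hs.plasma_concentration(short_params, 4.0, design.dose_times_h(), t)
        np.testing.assert_allclose(c4, 4.0 * c1, rtol=1e-12)


class TestExcretion:
    def test_interval_before_all_doses(self, short_params):
        amt = hs.excretion_interval(short_params, [(100.0, 1e6)], (0.0, 24.0))
        assert amt == 0.0

    def test_infinite_horizon_conservation(self, short_params):
        dose_ng = 5e5
        amt = hs.excretion_interval(short_params, [(0.0, dose_ng)], (0.0, 1e7))
        assert amt == pytest.approx(
            short_params.f_urine * short_params.f_abs * dose_ng, rel=1e-9
        )

    def test_single_dose_24h_against_quadrature(self):
        p = hs.PKParameters(ka=1.5, ke=0.1, v_over_f=4.0, f_urine=0.3)
        dose_ng = 1e6
        got = hs.excretion_interval(p, [(0.0, dose_ng)], (0.0, 24.0))
        # oracle: integrate the urinary elimination rate f_u*ke*A(t) where
        # A(t) = D_abs e^{-ke t} under instantaneous absorption
        rate = lambda t: p.f_urine * p.ke * p.f_abs * dose_ng * np.exp(-p.ke * t)
        expected, _ = quad(rate, 0.0, 24.0)
        assert got == pytest.approx(expected, rel=1e-6)
        assert got == pytest.approx(
            p.f_urine * p.f_abs * dose_ng * (1 - np.exp(-2.4)), rel=1e-9
        )

    def test_negative_interval_rejected(self, short_params):
        with pytest.raises(ValueError):
            hs.excretion_interval(short_params, [(0.0, 1.0)], (5.0, 5.0))

    def test_mass_balance_all_routes(self, design):
        """urine + faeces (incl. unabsorbed) = D_abs(f_u+f_f) + D(1-f_abs)."""
        p = hs.PKParameters(ka=1.5, ke=0.3, v_over_f=4.0,
                            f_abs=0.85, f_urine=0.35, f_faeces=0.25)
        schedule = [(t, 7e5) for t in design.dose_times_h()]
        total_dose = sum(d for _, d in schedule)
        horizon = (0.0, 1e6)
        urine = hs.excretion_interval(p, schedule, horizon, "urine")
        faeces = hs.excretion_interval(p, schedule, horizon, "faeces")
        expected = (
            p.f_abs * total_dose * (p.f_urine + p.f_faeces)
            + (1 - p.f_abs) * total_dose
        )
        assert urine + faeces == pytest.approx(expected, rel=5e-3)


class TestHairDeposition:
    def test_zero_exposure_deposits_nothing(self, short_params):
        rng = np.random.default_rng(0)
        assert hs.simulate_hair(short_params, 0.0, rng) == 0.0

    def test_noise_free_arithmetic(self):
        p = hs.PKParameters(ka=1.5, ke=0.35, v_over_f=4.0,
                            incorporation_coeff=0.42, bsv_sigma=0.0)
        rng = np.random.default_rng(0)
        assert hs.simulate_hair(p, 100.0, rng) == pytest.approx(42.0)

    def test_lognormal_mean_identity(self):
        """Mean-one noise: sample mean of value/auc converges to the coefficient."""
        p = hs.PKParameters(ka=1.5, ke=0.35, v_over_f=4.0,
                            incorporation_coeff=0.42, bsv_sigma=0.2)
        rng = np.random.default_rng(123)
        draws = np.array([hs.simulate_hair(p, 100.0, rng) for _ in range(10_000)])
        ratios = draws / 100.0
        se = ratios.std() / np.sqrt(len(ratios))
        assert abs(ratios.mean() - 0.42) < 3 * se


class TestSimulateStudy:
    def test_same_seed_identical_output(self, panel_by_name, small_design, pk_map, meas):
        sub = [panel_by_name["furosemide"]]
        a = hs.simulate_study(sub, small_design, pk_map, meas, seed=11)
        b = hs.simulate_study(sub, small_design, pk_map, meas, seed=11)
        assert a.responses.equals(b.responses)
        assert a.true_concentrations.equals(b.true_concentrations)

    def test_different_seed_differs(self, panel_by_name, small_design, pk_map, meas):
        sub = [panel_by_name["furosemide"]]
        a = hs.simulate_study(sub, small_design, pk_map, meas, seed=11)
        b = hs.simulate_study(sub, small_design, pk_map, meas, seed=12)
        assert not a.responses.equals(b.responses)

    def test_degenerate_noise_measures_truth(self, panel_by_name, small_design, pk_map):
        quiet = hs.MeasurementModel(proportional_cv=0.0, calibration_cv=0.0,
                                    blank_sd=1e-12)
        pk0 = {k: dataclasses.replace(v, bsv_sigma=0.0) for k, v in pk_map.items()}
        study = hs.simulate_study(
            [panel_by_name["furosemide"]], small_design, pk0, quiet, seed=3
        )
        samples = study.responses[study.responses["role"] == "sample"]
        merged = samples.merge(
            study.true_concentrations,
            on=["substance", "matrix", "animal_id", "group", "day", "time_h"],
        )
        np.testing.assert_allclose(
            merged["response_ratio"], merged["value"], rtol=1e-6, atol=1e-9
        )

    def test_vehicle_group_truth_all_zero(self, panel_by_name, small_design, pk_map, meas):
        study = hs.simulate_study(
            [panel_by_name["furosemide"]], small_design, pk_map, meas, seed=3
        )
        veh = study.true_concentrations.query("group == 'vehicle'")
        assert (veh["value"] == 0.0).all()

    def test_missing_pk_entry_raises(self, panel, small_design, meas):
        with pytest.raises(KeyError, match="missing PK"):
            hs.simulate_study(panel, small_design, {}, meas, seed=1)

    def test_calibration_sets_cover_range(self, panel_by_name, small_design, pk_map, meas):
        study = hs.simulate_study(
            [panel_by_name["furosemide"]], small_design, pk_map, meas, seed=3
        )
        cal = study.responses.query("role == 'calibrator'")
        for _, part in cal.groupby("matrix"):
            levels = np.sort(part["nominal_conc"].to_numpy())
            assert len(levels) == 15
            assert levels[0] == pytest.approx(0.01)
            assert levels[-1] == pytest.approx(500.0)

    def test_levels_are_geometric(self):
        levels = calibration_levels()
        ratios = levels[1:] / levels[:-1]
        np.testing.assert_allclose(ratios, ratios[0], rtol=1e-9)
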