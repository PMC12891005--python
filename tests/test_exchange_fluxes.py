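"""Carbon/phosphorus fluxes: Ct, PhiC, J calibration, PhiP, fits, binning."""

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import solve_ivp
from scipy.stats import linregress

import myconet as m
from myconet.exchange_fluxes import daily_uptake_ug
from tests.test_morphometry import make_snapshot


class TestCarbonContent:
    def test_unit_edge_carbon(self):
        params = m.CarbonParams(d_cell_g_per_cm3=1e-3, f_dry=1.0, f_carbon=1.0)
        # MC = 1 ug/mm^3; one edge r=1 um, L=1 um -> pi um^3 = pi*1e-9 mm^3
        snap = make_snapshot([[0, 0], [1, 0], [0, 1]], [1.0], [1.0])
        assert m.total_carbon(snap, params) == pytest.approx(np.pi * 1e-9)

    def test_empty_network_zero_carbon(self):
        snap = make_snapshot([[0, 0], [1, 0], [0, 1]], [], [])
        assert m.total_carbon(snap, m.CarbonParams()) == 0.0

    def test_matches_bruteforce_sum(self, rng):
        lengths = rng.uniform(50, 400, 25)
        radii = rng.uniform(1, 6, 25)
        spores = rng.uniform(15, 50, 4)
        snap = make_snapshot(rng.uniform(-1, 1, (5, 2)), lengths, radii,
                             spore_radii=spores)
        params = m.CarbonParams()
        brute = params.MC_ug_per_mm3 * 1e-9 * (
            np.sum(np.pi * radii**2 * lengths)
            + np.sum(4 / 3 * np.pi * spores**3)
        )
        assert m.total_carbon(snap, params) == pytest.approx(brute, rel=1e-12)

    def test_default_carbon_density_is_product_of_factors(self):
        params = m.CarbonParams()
        assert params.MC_ug_per_mm3 == pytest.approx(1.1 * 1e3 * 0.25 * 0.45)

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError):
            m.CarbonParams(cue=0.0)
        with pytest.raises(ValueError):
            m.CarbonParams(f_dry=1.5)


class TestCarbonFlux:
    def test_linear_ct_with_half_cue_doubles_rate(self):
        t = np.arange(0, 40, 2.0)
        phi, _ = m.carbon_flux(t, 0.7 * t, m.CarbonParams(cue=0.5),
                               smoothing_window_h=0)
        np.testing.assert_allclose(phi, 1.4, rtol=1e-9)

    def test_constant_ct_gives_zero(self):
        t = np.arange(0, 20, 2.0)
        phi, floored = m.carbon_flux(t, np.full_like(t, 5.0), m.CarbonParams(),
                                     smoothing_window_h=0)
        np.testing.assert_allclose(phi, 0.0)
        assert not floored.any()

    def test_quadratic_ct_matches_analytic_derivative(self):
        t = np.arange(0, 50, 2.0)
        ct = 0.01 * t**2
        phi, _ = m.carbon_flux(t, ct, m.CarbonParams(cue=1.0), smoothing_window_h=0)
        # central differences are exact for quadratics away from the ends
        np.testing.assert_allclose(phi[1:-1], 0.02 * t[1:-1], rtol=1e-9)

    def test_negative_derivative_floored_and_flagged(self):
        t = np.asarray([0.0, 2.0, 4.0, 6.0])
        ct = np.asarray([1.0, 2.0, 1.5, 1.6])
        phi, floored = m.carbon_flux(t, ct, m.CarbonParams(), smoothing_window_h=0)
        assert (phi >= 0).all()
        assert floored.any()

    def test_non_monotone_time_rejected(self):
        with pytest.raises(ValueError):
            m.carbon_flux([0.0, 2.0, 1.0], [1.0, 2.0, 3.0], m.CarbonParams())


class TestIntegratedSurface:
    def test_constant_surface(self):
        t = np.arange(0, 11, 1.0)
        assert m.integrated_surface(t, np.full_like(t, 4.0), 10.0) == pytest.approx(40.0)

    def test_linear_surface_exact_for_trapezoid(self):
        t = np.arange(0, 11, 1.0)
        assert m.integrated_surface(t, 2.0 * t, 10.0) == pytest.approx(100.0)

    def test_matches_fine_riemann_sum(self):
        t = np.linspace(0, 100, 51)
        s = np.sqrt(t) * 3.0
        coarse = m.integrated_surface(t, s, 100.0)
        fine_t = np.linspace(0, 100, 100_001)
        fine = np.trapezoid(np.interp(fine_t, t, s), fine_t)
        assert coarse == pytest.approx(fine, rel=1e-3)

    def test_tm_beyond_series_rejected(self):
        with pytest.raises(ValueError):
            m.integrated_surface([0.0, 10.0], [1.0, 1.0], 20.0)


class TestCalibration:
    def test_noiseless_assay_recovers_J_exactly(self, timelapse_200h):
        config = timelapse_200h.config.with_(assay_noise_sd_ug=0.0)
        assay = m.generate_depletion_assay(
            config, 3.0, np.linspace(25, 200, 8), timelapse=timelapse_200h
        )
        result = m.calibrate_J(assay, n_boot=50, seed=0)
        assert result.J_ng_per_mm2_h == pytest.approx(3.0, rel=1e-9)
        assert result.r_squared == pytest.approx(1.0)
        assert result.Pf0_ug == pytest.approx(config.P0_mass_ug, rel=1e-9)

    def test_degenerate_design_rejected(self):
        assay = pd.DataFrame(
            {"intS_mm2h": [5.0, 5.0, 5.0], "Pf_ug": [1.0, 2.0, 3.0]}
        )
        with pytest.raises(ValueError):
            m.calibrate_J(assay)

    def test_positive_slope_warns_no_depletion_signal(self):
        assay = pd.DataFrame(
            {"intS_mm2h": [1.0, 2.0, 3.0], "Pf_ug": [1.0, 2.0, 3.0]}
        )
        with pytest.warns(UserWarning):
            result = m.calibrate_J(assay, n_boot=10)
        assert result.no_depletion_signal or result.J_ng_per_mm2_h < 0

    def test_bootstrap_ci_covers_true_J(self, timelapse_200h):
        """Percentile-bootstrap CI contains the generating J in >= 90% of
        simulated assays at the default noise level."""
        harvest = np.linspace(25, 200, 8)
        hits = 0
        n_assays = 200
        for k in range(n_assays):
            config = timelapse_200h.config.with_(seed=k, assay_noise_sd_ug=0.5)
            assay = m.generate_depletion_assay(
                config, 3.0, harvest, timelapse=timelapse_200h
            )
            result = m.calibrate_J(assay, n_boot=250, seed=k)
            lo, hi = result.ci_ng_per_mm2_h
            hits += lo <= 3.0 <= hi
        assert hits / n_assays >= 0.90


class TestPhosphorusFlux:
    def test_worked_uptake_example_one_microgram_per_day(self):
        """1 m of hypha at r = 3 um with J = 3 ng/mm^2/h extracts ~1 ug/day."""
        uptake = daily_uptake_ug(1e6, 3.0, 3.0)
        assert round(uptake, 0) == 1.0
        assert uptake == pytest.approx(3.0 * 18.85 * 24 * 1e-3, rel=1e-3)

    def test_saturating_flux_is_J_times_surface(self):
        t = np.arange(0, 20, 2.0)
        s = np.full_like(t, 10.0)
        transport = m.TransportParams(Km_ug_per_ml=0.0)
        flux = m.phosphorus_flux(t, s, transport, P_budget_ug=1e6)
        np.testing.assert_allclose(
            flux["PhiP_ug_per_h"], 3.0 * 10.0 * 1e-3, rtol=1e-9
        )

    def test_cumulative_transfer_never_exceeds_budget(self):
        t = np.arange(0, 400, 2.0)
        s = np.full_like(t, 50.0)
        flux = m.phosphorus_flux(t, s, m.TransportParams(Km_ug_per_ml=0.0), 1.0)
        assert flux["cum_P_ug"].max() <= 1.0 + 1e-12
        assert flux["cum_P_ug"].iloc[-1] == pytest.approx(1.0, rel=1e-6)

    def test_matches_fine_ode_oracle_at_two_hour_sampling(self, timelapse_200h):
        """The explicit accessible-pool update agrees with a high-accuracy
        ODE solution of the Michaelis-Menten depletion law to < 1%."""
        truth = timelapse_200h.truth
        t = truth["t_h"].to_numpy()
        s = truth["S_mm2"].to_numpy()
        transport = m.TransportParams()
        budget = 4.0
        flux = m.phosphorus_flux(t, s, transport, budget)

        def rhs(tt, y):
            conc = max(y[0], 0.0) / transport.gel_volume_ml
            j = transport.Jmax_ng_per_mm2_h * conc / (conc + transport.Km_ug_per_ml)
            return [-j * np.interp(tt, t, s) * 1e-3]

        sol = solve_ivp(rhs, (t[0], t[-1]), [budget], t_eval=t, rtol=1e-10, atol=1e-12)
        cum_oracle = budget - sol.y[0]
        mask = cum_oracle > 1e-3
        rel = np.abs(flux["cum_P_ug"].to_numpy()[mask] - cum_oracle[mask]) / cum_oracle[mask]
        assert rel.max() < 0.01

    def test_negative_budget_rejected(self):
        with pytest.raises(ValueError):
            m.phosphorus_flux([0.0, 2.0], [1.0, 1.0], m.TransportParams(), -1.0)

    def test_transport_params_validate(self):
        with pytest.raises(ValueError):
            m.TransportParams(J_ng_per_mm2_h=5.0, Jmax_ng_per_mm2_h=3.0)


class TestMediaPhosphorus:
    def test_high_P_recipe(self):
        """28 mL full-strength medium: 96 ug total, 3.4 ug/mL, 1.4 accessible."""
        media = m.media_phosphorus(28.0, 4.1, 3.0, 27.0, 2.0)
        assert media.total_mass_ug == pytest.approx(96.0, abs=0.5)
        assert media.total_conc_ug_per_ml == pytest.approx(3.4, abs=0.05)
        assert media.accessible_conc_ug_per_ml == pytest.approx(1.4, abs=0.05)

    def test_low_P_recipe(self):
        """Dropping KH2PO4 leaves the Phytagel P: 70 ug, 2.5 ug/mL, 0.5."""
        media = m.media_phosphorus(28.0, 0.0, 3.0, 27.0, 2.0)
        assert media.total_mass_ug == pytest.approx(70.0, abs=0.5)
        assert media.total_conc_ug_per_ml == pytest.approx(2.5, abs=0.05)
        assert media.accessible_conc_ug_per_ml == pytest.approx(0.5, abs=0.05)

    def test_no_sources_no_phosphorus(self):
        media = m.media_phosphorus(28.0, 0.0, 0.0, 27.0, 0.0)
        assert media.total_mass_ug == 0.0
        assert media.accessible_conc_ug_per_ml == 0.0

    def test_accessible_floored_at_zero(self):
        media = m.media_phosphorus(28.0, 0.0, 1.0, 27.0, 50.0)
        assert media.accessible_conc_ug_per_ml == 0.0


class TestExchangeRatioFit:
    def test_exact_proportionality_recovered_with_zero_width_ci(self):
        phi_p = np.asarray([0.5, 1.0, 2.0, 4.0])
        slope, ci = m.exchange_ratio_fit(3.0 * phi_p, phi_p, n_boot=100, seed=0)
        assert slope == pytest.approx(3.0, rel=1e-12)
        assert ci[1] - ci[0] == pytest.approx(0.0, abs=1e-12)

    def test_single_point_through_origin(self):
        slope, _ = m.exchange_ratio_fit([2.0], [1.0], n_boot=10, seed=0)
        assert slope == pytest.approx(2.0)

    def test_matches_gridsearch_least_squares_oracle(self, rng):
        phi_p = rng.uniform(0.1, 5.0, 40)
        phi_c = 2.7 * phi_p + rng.normal(0, 0.3, 40)
        slope, _ = m.exchange_ratio_fit(phi_c, phi_p, n_boot=10, seed=0)
        grid = np.linspace(1.0, 5.0, 400_001)
        sse = ((phi_c[:, None] - grid[None, :] * phi_p[:, None]) ** 2).sum(axis=0)
        assert slope == pytest.approx(grid[sse.argmin()], abs=1e-5)

    def test_scale_equivariance(self, rng):
        phi_p = rng.uniform(0.1, 5.0, 30)
        phi_c = 3.0 * phi_p + rng.normal(0, 0.2, 30)
        s1, _ = m.exchange_ratio_fit(phi_c, phi_p, n_boot=10, seed=0)
        s2, _ = m.exchange_ratio_fit(phi_c, 10.0 * phi_p, n_boot=10, seed=0)
        assert s2 == pytest.approx(s1 / 10.0, rel=1e-9)

    def test_all_zero_phi_p_rejected(self):
        with pytest.raises(ValueError):
            m.exchange_ratio_fit([1.0, 2.0], [0.0, 0.0], n_boot=10)

    def test_free_intercept_variant(self, rng):
        phi_p = rng.uniform(0.1, 5.0, 50)
        phi_c = 2.0 * phi_p + 1.0
        slope, _ = m.exchange_ratio_fit(phi_c, phi_p, through_origin=False,
                                        n_boot=10, seed=0)
        assert slope == pytest.approx(2.0, rel=1e-9)

    def test_kappa_recovered_from_proportional_generator_data(self, timelapse_200h):
        """Flux series built with proportional exchange return the generating
        exchange rate within 2% at zero noise."""
        truth = timelapse_200h.truth
        s = truth["S_mm2"].to_numpy()
        phi_p = 3.0 * s * 1e-3
        phi_c = 3.0 * phi_p
        slope, _ = m.exchange_ratio_fit(phi_c, phi_p, n_boot=10, seed=0)
        assert slope == pytest.approx(3.0, rel=0.02)


class TestBinnedAverage:
    def test_constant_series(self):
        t = np.arange(0, 30, 2.0)
        out = m.binned_average(t, np.full_like(t, 4.0), 10.0)
        np.testing.assert_allclose(out["mean"], 4.0)
        np.testing.assert_allclose(out["sem"], 0.0)

    def test_two_values_in_one_bin(self):
        out = m.binned_average([1.0, 2.0], [1.0, 3.0], 10.0)
        assert len(out) == 1
        assert out["mean"].iloc[0] == pytest.approx(2.0)
        assert out["sem"].iloc[0] == pytest.approx(1.0)
        assert out["ci_lo"].iloc[0] == pytest.approx(0.0)
        assert out["ci_hi"].iloc[0] == pytest.approx(4.0)

    def test_seven_point_hand_fixture(self):
        t = [0, 2, 4, 12, 14, 16, 25]
        v = [1.0, 2.0, 3.0, 10.0, 12.0, 14.0, 7.0]
        out = m.binned_average(t, v, 10.0)
        assert len(out) == 3
        np.testing.assert_allclose(out["mean"], [2.0, 12.0, 7.0])
        np.testing.assert_allclose(out["n"], [3, 3, 1])
        assert out["sem"].iloc[0] == pytest.approx(1.0 / np.sqrt(3))
        assert out["sem"].iloc[2] == 0.0

    def test_empty_bins_omitted(self):
        out = m.binned_average([1.0, 55.0], [1.0, 2.0], 10.0)
        np.testing.assert_allclose(out["bin_left_h"], [0.0, 50.0])


class TestFluxSeries:
    def test_end_to_end_series_well_formed(self, timelapse_100h):
        series = m.compute_flux_series(
            timelapse_100h.snapshots,
            m.CarbonParams(),
            m.TransportParams(),
            P_budget_ug=40.0,
        )
        assert (series["Ct_ug"].diff().dropna() >= -1e-12).all()
        assert (series["PhiP_ug_per_h"] >= 0).all()
        kappa = series["kappa"].dropna()
        assert len(kappa) > 0 and np.isfinite(kappa).all()
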