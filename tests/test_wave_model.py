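"""Traveling-wave model: numerics, conservation, feedback, regime formulas."""

import numpy as np
import pytest
from scipy.stats import linregress

import myconet as m
from myconet.wave_model import (
    WaveModelState,
    depletion_width,
    front_position_mm,
    initial_state,
)


@pytest.fixture(scope="module")
def regime2_run():
    """Feedback off, no spores, P plentiful: pure traveling-wave scalings."""
    params = m.default_params(
        150.0, Rmax_mm=120.0, kI_per_h=0.0, sigma_spore_ug_per_um_h=0.0,
        P0_conc_ug_per_ml=20.0,
    )
    return m.run_simulation(params, 600.0)


@pytest.fixture(scope="module")
def regime3_run():
    """Feedback off, no spores, low P: co-moving depletion front."""
    params = m.default_params(
        150.0, Rmax_mm=200.0, kI_per_h=0.0, sigma_spore_ug_per_um_h=0.0,
        P0_conc_ug_per_ml=0.5,
    )
    return m.run_simulation(params, 800.0, store_fields=True)


class TestParams:
    def test_cfl_violation_rejected(self):
        with pytest.raises(ValueError, match="CFL"):
            m.WaveModelParams(advection_mm_per_h=2.0, dt_h=1.0, dR_mm=0.5)
        with pytest.raises(ValueError, match="CFL"):
            m.WaveModelParams(diffusion_mm2_per_h=1.0, dt_h=1.0, dR_mm=0.5)

    def test_negative_rates_rejected(self):
        with pytest.raises(ValueError):
            m.WaveModelParams(alpha0_per_h=-0.1)

    def test_radius_follows_speed_law(self):
        params = m.default_params(150.0)
        assert params.mean_radius_um == pytest.approx(0.01 * 150 + 1.5)
        assert m.default_params(300.0).mean_radius_um == pytest.approx(4.5)

    def test_cell_areas_tile_the_disk(self):
        params = m.default_params(150.0, Rmax_mm=50.0)
        assert params.cell_areas_mm2().sum() == pytest.approx(np.pi * 50.0**2)


class TestStep:
    def test_quiescent_state_is_a_fixed_point(self):
        params = m.default_params(150.0, Rmax_mm=20.0)
        state = initial_state(params)
        state.n[:] = 0.0
        out = m.step(state, params)
        np.testing.assert_array_equal(out.rho, state.rho)
        np.testing.assert_array_equal(out.P, state.P)
        assert out.alpha_per_h == state.alpha_per_h

    def test_pure_advection_moves_pulse_at_advection_speed(self):
        params = m.WaveModelParams(
            alpha0_per_h=0.0, beta_mm2_per_um_h=0.0, diffusion_mm2_per_h=0.0,
            advection_mm_per_h=0.2, vg_um_per_h=0.0, kI_per_h=0.0,
            Rmax_mm=40.0, dR_mm=0.25, dt_h=0.25,
        )
        state = initial_state(params)
        grid = params.grid_mm()
        state.n = np.exp(-((grid - 5.0) ** 2) / 2.0)
        areas = params.cell_areas_mm2()

        def center(s):
            return float(np.sum(grid * s.n * areas) / np.sum(s.n * areas))

        c0 = center(state)
        for _ in range(200):  # 50 h
            state = m.step(state, params)
        drift = (center(state) - c0) / 50.0
        assert drift == pytest.approx(params.advection_mm_per_h, rel=0.1)

    def test_per_step_P_bookkeeping_is_exact(self):
        params = m.default_params(150.0, Rmax_mm=30.0)
        state = initial_state(params)
        state.rho[:20] = 500.0
        before = state.P.copy()
        out = m.step(state, params)
        removed_mass = float(
            np.sum((before - out.P) * params.cell_areas_mm2() * params.gel_depth_mm)
            * 1e-3
        )
        assert removed_mass == pytest.approx(out.phi_p_ug_per_h * params.dt_h, rel=1e-9)

    def test_fields_stay_non_negative(self, regime3_run):
        state = regime3_run.final_state
        assert (state.rho >= 0).all()
        assert (state.n >= 0).all()
        assert (state.P >= 0).all()
        assert (state.P <= regime3_run.params.P0_conc_ug_per_ml + 1e-12).all()


class TestConservation:
    def test_total_P_balance_closes(self, regime3_run):
        """Field deficit x gel volume equals cumulative transferred P."""
        params = regime3_run.params
        state = regime3_run.final_state
        vols = params.cell_areas_mm2() * params.gel_depth_mm
        deficit = float(np.sum((params.P0_conc_ug_per_ml - state.P) * vols) * 1e-3)
        assert deficit == pytest.approx(state.P_transferred_ug, rel=1e-6)


class TestFrontSpeed:
    def test_default_run_travels_near_nominal_speed(self, default_simulation):
        assert abs(default_simulation.v_wave_um_per_h - 150.0) / 150.0 < 0.10
        assert default_simulation.v_wave_r_squared > 0.99

    def test_both_study_speeds_realised(self):
        for v_nom, rmax in [(150.0, 80.0), (300.0, 140.0)]:
            res = m.run_simulation(
                m.default_params(v_nom, Rmax_mm=rmax, kI_per_h=0.0), 300.0
            )
            assert abs(res.v_wave_um_per_h - v_nom) / v_nom < 0.10

    def test_grid_convergence_of_wave_speed(self):
        """Halving the grid spacing and timestep moves the speed < 3%."""
        p1 = m.default_params(150.0, Rmax_mm=80.0, kI_per_h=0.0)
        p2 = p1.with_(dR_mm=p1.dR_mm / 2, dt_h=p1.dt_h / 2)
        v1 = m.run_simulation(p1, 300.0).v_wave_um_per_h
        v2 = m.run_simulation(p2, 300.0).v_wave_um_per_h
        assert abs(v2 - v1) / v1 < 0.03


class TestFeedback:
    def test_exchange_ratio_held_at_setpoint_after_settling(self, default_simulation):
        saves = default_simulation.saves
        settled = saves[saves["t_h"] > 600.0]["kappa"]
        assert (np.abs(settled - 3.0) / 3.0 < 0.05).all()

    def test_through_origin_slope_matches_setpoint(self, default_simulation):
        saves = default_simulation.saves
        late = saves[saves["t_h"] > 300.0]
        slope, _ = m.exchange_ratio_fit(
            late["PhiC_ug_per_h"], late["PhiP_ug_per_h"], n_boot=10, seed=0
        )
        assert abs(slope - 3.0) / 3.0 < 0.05

    def test_alpha_stays_within_clamp(self, default_simulation):
        alpha = default_simulation.saves["alpha_per_h"]
        assert (alpha >= 0).all()
        assert (alpha <= default_simulation.params.alpha_max_per_h).all()

    def test_saturated_density_increases_with_P_availability(self):
        """At fixed exchange rate, richer substrate supports denser growth."""
        rho_cs = []
        for p0 in (0.5, 1.4, 2.8):
            params = m.default_params(150.0, Rmax_mm=150.0, P0_conc_ug_per_ml=p0)
            res = m.run_simulation(params, 700.0)
            state = res.final_state
            grid = res.grid_mm
            r_front = res.saves["R_front_mm"].iloc[-1]
            zone = (grid > 0.5 * r_front) & (grid < 0.9 * r_front)
            rho_cs.append(state.rho[zone].mean())
        assert rho_cs[0] < rho_cs[1] < rho_cs[2]


class TestRegimeScalings:
    def test_regime2_flux_ratio_scales_inversely_with_wave_radius(self, regime2_run):
        """Without spore carbon, PhiC/PhiP ~ 1/R_wave (log-log slope -1)."""
        saves = regime2_run.saves
        sel = (
            (saves["t_h"] > 150.0)
            & (saves["dR_mm"] >= 0.95 * saves["R_front_mm"])
            & (saves["PhiP_ug_per_h"] > 0)
        )
        fit = linregress(
            np.log(saves.loc[sel, "R_front_mm"]), np.log(saves.loc[sel, "kappa"])
        )
        assert fit.slope == pytest.approx(-1.0, abs=0.1)
        assert fit.rvalue**2 > 0.99

    def test_regime3_ratio_converges_to_closed_form(self, regime3_run):
        """Once the depletion front co-moves, kappa settles to
        rho_C / (CUE [P]0 d) within 10%."""
        params = regime3_run.params
        state = regime3_run.final_state
        saves = regime3_run.saves
        grid = regime3_run.grid_mm
        r_front = saves["R_front_mm"].iloc[-1]
        zone = (grid > 0.3 * r_front) & (grid < 0.7 * r_front)
        q = (params.carbon.MC_ug_per_mm3 * np.pi * params.xi
             * params.mean_radius_um**2 * 1e-9)
        kappa_pred = m.analytic_regime3_ratio(
            q * state.rho[zone].mean(), params.carbon.cue,
            params.P0_conc_ug_per_ml, params.gel_depth_mm,
        )
        kappa_sim = saves["kappa"].iloc[-20:].mean()
        assert abs(kappa_sim - kappa_pred) / kappa_pred < 0.10

    def test_depletion_width_stabilises_in_regime3(self, regime3_run):
        saves = regime3_run.saves
        assert np.isfinite(regime3_run.t1_h)
        tail = saves[saves["t_h"] > saves["t_h"].max() - 100.0]["dR_mm"]
        assert np.ptp(tail) / tail.mean() < 0.15

    def test_annulus_formula_consistent_with_simulation(self, regime3_run):
        """PhiP = J 2 pi rho_S R dR reproduces the simulated supply when dR
        is the uptake-equivalent width and rho_S the annulus density."""
        params = regime3_run.params
        saves = regime3_run.saves
        grid = regime3_run.grid_mm
        i = (saves["t_h"] - 600.0).abs().idxmin()
        row = saves.loc[i]
        state = WaveModelState(
            t_h=row["t_h"], rho=regime3_run.fields["rho"][i],
            n=regime3_run.fields["n"][i], P=regime3_run.fields["P"][i],
            alpha_per_h=row["alpha_per_h"],
        )
        width = depletion_width(state, params, method="uptake")
        conc = np.maximum(state.P, 0.0)
        j_rel = conc / (conc + params.Km_ug_per_ml)
        j_rel /= params.P0_conc_ug_per_ml / (params.P0_conc_ug_per_ml + params.Km_ug_per_ml)
        inside = grid <= row["R_front_mm"]
        rho_ann = float(
            np.sum((j_rel * state.rho)[inside]) / np.sum(j_rel[inside])
        )
        rho_s = 2 * np.pi * params.mean_radius_um * rho_ann * 1e-6
        j0 = params.Jmax_ng_per_mm2_h * params.P0_conc_ug_per_ml / (
            params.P0_conc_ug_per_ml + params.Km_ug_per_ml
        )
        _, phi_p = m.analytic_regime2_fluxes(
            0.0, 150.0, row["R_front_mm"], 0.0, j0, rho_s, width, params.carbon.cue
        )
        assert phi_p == pytest.approx(row["PhiP_ug_per_h"], rel=0.15)

    def test_regime_boundaries_ordered(self, regime3_run):
        assert regime3_run.t0_h < regime3_run.t1_h


class TestAnalyticFormulas:
    def test_regime2_algebra(self):
        phi_c, phi_p = m.analytic_regime2_fluxes(
            rho_c_ug_per_mm2=0.01, v_wave_um_per_h=150.0, r_wave_mm=10.0,
            spore_term_ug_per_h=0.0, J_ng_per_mm2_h=3.0, rho_s=0.02,
            delta_r_mm=10.0, cue=0.5,
        )
        assert phi_c == pytest.approx(2 * np.pi * 0.02 * 0.15 * 10.0)
        assert phi_p == pytest.approx(3e-3 * 2 * np.pi * 0.02 * 100.0)

    def test_ratio_decays_as_inverse_radius_in_regime2(self):
        ratios = []
        for r_wave in (5.0, 10.0, 20.0):
            phi_c, phi_p = m.analytic_regime2_fluxes(
                0.01, 150.0, r_wave, 0.0, 3.0, 0.02, r_wave, 0.5
            )
            ratios.append(phi_c / phi_p * r_wave)
        np.testing.assert_allclose(ratios, ratios[0], rtol=1e-12)

    def test_zero_wave_speed_leaves_only_spore_carbon(self):
        phi_c, _ = m.analytic_regime2_fluxes(0.01, 0.0, 10.0, 0.7, 3.0, 0.02, 10.0, 0.5)
        assert phi_c == pytest.approx(0.7)

    def test_regime3_arithmetic(self):
        # rho_C = 1 ug/mm^2, CUE = 0.5, [P]0 = 1000 ug/mL = 1 ug/mm^3, d = 2 mm
        assert m.analytic_regime3_ratio(1.0, 0.5, 1000.0, 2.0) == pytest.approx(1.0)

    def test_regime3_linear_in_carbon_density(self):
        one = m.analytic_regime3_ratio(0.01, 0.5, 1.4, 2.5)
        two = m.analytic_regime3_ratio(0.02, 0.5, 1.4, 2.5)
        assert two == pytest.approx(2 * one)

    def test_regime3_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            m.analytic_regime3_ratio(1.0, 0.5, 0.0, 2.0)


class TestDepletionWidth:
    def test_uniform_P_gives_full_wave_radius(self):
        params = m.default_params(150.0, Rmax_mm=30.0)
        state = initial_state(params)
        state.rho[:40] = 100.0  # colonised out to 10 mm
        width = depletion_width(state, params)
        assert width == pytest.approx(front_position_mm(state, params))

    def test_depleted_core_leaves_annulus(self):
        params = m.default_params(150.0, Rmax_mm=30.0)
        state = initial_state(params)
        grid = params.grid_mm()
        state.rho[grid <= 10.0] = 100.0
        state.P[grid <= 6.0] = 0.0
        width = depletion_width(state, params)
        front = front_position_mm(state, params)
        assert width == pytest.approx(front - 6.0, abs=params.dR_mm)

    def test_no_front_gives_zero(self):
        params = m.default_params(150.0, Rmax_mm=30.0)
        state = initial_state(params)
        assert depletion_width(state, params) == 0.0

    def test_uptake_width_matches_threshold_when_sharp(self):
        params = m.default_params(150.0, Rmax_mm=30.0, Km_ug_per_ml=0.0)
        state = initial_state(params)
        grid = params.grid_mm()
        state.rho[grid <= 10.0] = 100.0
        state.P[grid <= 6.0] = 0.0
        sharp = depletion_width(state, params, method="uptake")
        assert sharp == pytest.approx(depletion_width(state, params), abs=params.dR_mm)
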