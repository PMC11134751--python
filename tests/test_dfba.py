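"""Dynamic FBA: kinetic switching rules, Euler integration, carbon
conservation and kinetic parameter recovery."""

import numpy as np
import pytest

from tubigem import (FermentationModel, FermentationState, KineticParameters,
                     apply_kinetic_bounds, carbon_balance, dfba_step,
                     glucose_uptake_bound, make_fermentation_dataset,
                     make_toy_model, run_dfba, xylose_uptake_bound)
from tubigem.dfba import xylose_uptake_components
from tubigem.units import g_per_l_to_mm


@pytest.fixture(scope="module")
def params():
    return KineticParameters()


def initial_state(p, **overrides):
    base = dict(t=p.t_start, biomass=0.05, glucose=80.0, xylose=40.0,
                citrate=0.0, phosphate=2.0)
    base.update(overrides)
    return FermentationState(**base)


class TestUptakeKinetics:
    def test_no_glucose_no_uptake(self, params):
        assert glucose_uptake_bound(0.0, params) == 0.0

    def test_high_affinity_only_below_threshold(self, params):
        # 70 g/L with vmax 2, km 0.1: 2*70/70.1
        assert glucose_uptake_bound(70.0, params) == pytest.approx(
            2 * 70 / 70.1, abs=1e-6)
        assert glucose_uptake_bound(70.0, params) == pytest.approx(1.9971, abs=1e-4)

    def test_low_affinity_term_added_above_75(self, params):
        high_only = params.vmax_glc_high * 80 / (params.km_glc_high + 80)
        both = glucose_uptake_bound(80.0, params)
        assert both == pytest.approx(
            high_only + params.vmax_glc_low * 80 / (params.km_glc_low + 80))
        assert both > high_only

    def test_threshold_is_strict(self, params):
        at = glucose_uptake_bound(75.0, params)
        above = glucose_uptake_bound(75.000001, params)
        assert above - at > 0.5  # discontinuous activation

    def test_xylose_zero_concentration(self, params):
        assert xylose_uptake_bound(0.0, 0.0, params) == 0.0

    def test_transporter_repressed_at_high_glucose(self, params):
        # 80 g/L glucose is ~444 mM, far above the 5 mM threshold
        passive, transporter = xylose_uptake_components(
            40.0, g_per_l_to_mm(80.0, "glucose"), params)
        assert transporter == 0.0
        assert passive == pytest.approx(params.k_passive_xyl * 40.0)

    def test_transporter_active_at_low_glucose(self, params):
        passive, transporter = xylose_uptake_components(10.0, 1.0, params)
        assert transporter == pytest.approx(
            params.vmax_xyl * 10 / (params.km_xyl + 10))
        assert xylose_uptake_bound(10.0, 1.0, params) == pytest.approx(
            passive + transporter)

    def test_negative_parameters_rejected(self):
        with pytest.raises(ValueError):
            KineticParameters(vmax_glc_high=-1)


class TestApplyKineticBounds:
    def test_ngam_set_on_maintenance_reaction(self, toy_model, params):
        bounded = apply_kinetic_bounds(toy_model, initial_state(params), params)
        assert bounded.reaction("ATPM").lower_bound == pytest.approx(1.9)

    def test_phosphate_depletion_closes_uptake(self, toy_model, params):
        state = initial_state(params, phosphate=0.0)
        bounded = apply_kinetic_bounds(toy_model, state, params)
        assert bounded.reaction("EX_pi_e").lower_bound == 0.0
        from tubigem import optimize
        assert optimize(bounded).objective_value == pytest.approx(0.0, abs=1e-6)

    def test_zero_concentrations_close_all_substrates(self, toy_model, params):
        state = initial_state(params, glucose=0.0, xylose=0.0, phosphate=0.0)
        bounded = apply_kinetic_bounds(toy_model, state, params)
        for rid in ("EX_glc__D_e", "EX_xyl__D_e", "EX_pi_e"):
            assert bounded.reaction(rid).lower_bound == 0.0

    def test_original_model_unmodified(self, toy_model, params):
        apply_kinetic_bounds(toy_model, initial_state(params), params)
        assert toy_model.reaction("ATPM").lower_bound == 0.0

    def test_missing_role_reaction_named(self, chain_model, params):
        with pytest.raises(KeyError, match="glucose_exchange"):
            apply_kinetic_bounds(chain_model, initial_state(params), params)


class TestDfbaStep:
    def test_euler_biomass_update(self, toy_model, params):
        state = initial_state(params, biomass=1.0)
        new, diag = dfba_step(toy_model, state, params, dt=0.1)
        assert new.biomass == pytest.approx(1.0 * (1 + diag["mu"] * 0.1))
        assert new.t == pytest.approx(state.t + 0.1)

    def test_euler_glucose_update_uses_molar_mass(self, toy_model, params):
        state = initial_state(params, biomass=1.0)
        new, diag = dfba_step(toy_model, state, params, dt=1.0)
        expected = 80.0 + diag["v_glc"] * 1.0 * 1.0 * 180.16 / 1000.0
        assert new.glucose == pytest.approx(expected)
        # uptake of 2 mmol/gDW/h at 1 gDW/L for 1 h removes 0.36032 g/L
        assert 80.0 - new.glucose == pytest.approx(
            -diag["v_glc"] * 0.18016, rel=1e-9)

    def test_zero_biomass_leaves_concentrations_unchanged(self, toy_model, params):
        state = initial_state(params, biomass=0.0)
        new, _ = dfba_step(toy_model, state, params, dt=0.5)
        assert (new.glucose, new.xylose, new.citrate, new.phosphate) == (
            80.0, 40.0, 0.0, 2.0)
        assert new.biomass == 0.0


@pytest.fixture(scope="module")
def trajectory(toy_model):
    p = KineticParameters()
    return run_dfba(toy_model, p, initial_state(p), t_end=120.0, dt=0.2), p


class TestRunDfba:
    def test_sequential_sugar_use(self, trajectory):
        """Transporter-mediated xylose uptake is exactly 0 while glucose
        exceeds the 5 mM repression threshold."""
        traj, p = trajectory
        diag = traj.diagnostics_frame()
        above = diag[diag["glc_mM"] > p.xyl_repression_threshold]
        assert len(above) > 100
        assert (above["xyl_uptake_transporter"] == 0.0).all()
        below = diag[diag["glc_mM"] <= p.xyl_repression_threshold]
        assert (below["xyl_uptake_transporter"] > 0).any()

    def test_sugars_non_increasing_biomass_non_decreasing(self, trajectory):
        traj, _ = trajectory
        df = traj.to_dataframe()
        assert (df["glucose"].diff().dropna() <= 1e-9).all()
        assert (df["xylose"].diff().dropna() <= 1e-9).all()
        assert (df["biomass"].diff().dropna() >= -1e-9).all()

    def test_time_strictly_increasing_from_t_start(self, trajectory):
        traj, p = trajectory
        df = traj.to_dataframe()
        assert df["t"].iloc[0] == p.t_start
        assert (df["t"].diff().dropna() > 0).all()

    def test_no_negative_concentrations(self, trajectory):
        traj, _ = trajectory
        df = traj.to_dataframe()
        assert (df[["biomass", "glucose", "xylose", "citrate", "phosphate"]]
                >= 0).all().all()

    def test_phosphate_exhaustion_triggers_citrate_phase(self, trajectory):
        traj, _ = trajectory
        diag = traj.diagnostics_frame()
        assert set(diag["phase"]) == {"growth", "citrate"}
        assert traj.final.citrate > 10.0

    def test_carbon_recovery_is_one(self, trajectory, toy_model):
        traj, _ = trajectory
        recovery = carbon_balance(traj, toy_model)
        recovery = recovery.dropna()
        assert len(recovery) > 100
        assert np.allclose(recovery, 1.0, atol=1e-3)

    def test_zero_inoculum_flat_trajectory(self, toy_model):
        p = KineticParameters()
        traj = run_dfba(toy_model, p, initial_state(p, biomass=0.0),
                        t_end=15.0, dt=0.5)
        df = traj.to_dataframe()
        assert (df["glucose"] == 80.0).all()
        assert (df["biomass"] == 0.0).all()

    def test_clean_termination_on_substrate_exhaustion(self, toy_model):
        """NGAM becomes unsatisfiable once everything is consumed; the run
        truncates cleanly rather than producing negative concentrations."""
        p = KineticParameters()
        start = initial_state(p, glucose=0.5, xylose=0.0, phosphate=0.05)
        traj = run_dfba(toy_model, p, start, t_end=400.0, dt=0.5)
        assert traj.termination.startswith("infeasible")
        df = traj.to_dataframe()
        assert (df[["glucose", "xylose", "phosphate"]] >= 0).all().all()

    def test_dt_refinement_converges(self, toy_model):
        """Halving dt changes endpoint concentrations by < 1 %."""
        p = KineticParameters()
        coarse = run_dfba(toy_model, p, initial_state(p), t_end=40.0, dt=0.2)
        fine = run_dfba(toy_model, p, initial_state(p), t_end=40.0, dt=0.1)
        for field in ("biomass", "glucose", "citrate"):
            a = getattr(coarse.final, field)
            b = getattr(fine.final, field)
            assert abs(a - b) / max(abs(b), 1e-9) < 0.01

    def test_start_time_mismatch_rejected(self, toy_model):
        p = KineticParameters()
        with pytest.raises(ValueError, match="t_start"):
            run_dfba(toy_model, p, initial_state(p, t=0.0), t_end=20.0)


class TestParameterRecovery:
    def test_vmax_glc_high_recovered_within_ten_percent(self, toy_model):
        """Seeded fit to 2 % multiplicative noise recovers the truth."""
        truth = KineticParameters()
        samples, _ = make_fermentation_dataset(truth, noise_cv=0.02, seed=42,
                                               model=toy_model)
        fm = FermentationModel(toy_model,
                               params=truth.replace(vmax_glc_high=1.4))
        result = fm.fit(samples[["t", "glucose"]],
                        param_names=("vmax_glc_high",), species=("glucose",))
        estimate = result.params["vmax_glc_high"]
        assert abs(estimate - truth.vmax_glc_high) / truth.vmax_glc_high < 0.10
        assert result.bse["vmax_glc_high"] > 0
        assert result.success

    def test_summary_reports_estimate(self, toy_model):
        truth = KineticParameters()
        samples, _ = make_fermentation_dataset(truth, noise_cv=0.0, seed=1,
                                               model=toy_model)
        fm = FermentationModel(toy_model, params=truth)
        result = fm.fit(samples[["t", "glucose"]], n_grid=1)
        text = result.summary()
        assert "vmax_glc_high" in text and "std err" in text
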