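"""Tests of the inflammation network RHS, steady state, migration
topology, and the scenario integrator (events, death root-finding,
non-negativity, mass balance, export format)."""

import numpy as np
import pandas as pd
import pytest

from hemotwin import (
    DEATH_THRESHOLD,
    InjuryEvent,
    Scenario,
    SolverOptions,
    healthy_steady_state,
    inflammation_rhs,
    integrate_scenario,
    migration_fluxes,
)
from hemotwin.model_core import IDX, N_STATES, STATE_NAMES, ModelState, rhs_vector

from conftest import make_constant_damage_params, make_constant_damage_scenario


class TestHealthySteadyState:
    def test_active_pools_and_pro_cytokines_zero(self, params):
        s = healthy_steady_state(params)
        for name in STATE_NAMES:
            if name.endswith("_a") or "_a_" in name or name.startswith(("tnf", "il1", "il6")):
                assert s[name] == 0.0, name
        assert s.trauma == 0.0 and s.damp == 0.0 and s.clot == 0.0

    def test_rhs_vanishes_at_steady_state(self, params):
        s = healthy_steady_state(params)
        d = inflammation_rhs(s, params)
        assert np.abs(d.vector).max() < 1e-9

    def test_negative_parameter_rejected(self, params):
        with pytest.raises(ValueError, match="cyto.k_tnf"):
            params.with_updates({"cyto.k_tnf": -1.0})

    def test_isolated_il6_perturbation_decays(self, params):
        """+1 pg/mL IL-6 with no trauma relaxes back within 1% in 120 min."""
        s = healthy_steady_state(params)
        s.il6_blood = 1.0
        scen = Scenario(t_initial=0.0, horizon=120.0)
        p = params.namespace()
        from scipy.integrate import solve_ivp

        sol = solve_ivp(rhs_vector, (0, 120.0), s.vector, args=(p,),
                        method="LSODA", rtol=1e-8, atol=1e-11)
        end = ModelState(sol.y[:, -1])
        assert end.il6_blood < 0.01  # IL-6 itself decayed
        ref = healthy_steady_state(params).vector
        scale = np.maximum(np.abs(ref), 1.0)
        assert np.abs((end.vector - ref) / scale).max() < 0.01


class TestInflammationEdges:
    def test_no_sources_without_stimulus(self, params):
        d = inflammation_rhs(healthy_steady_state(params), params)
        assert np.abs(d.vector).max() < 1e-12

    def test_trauma_activates_monocytes_in_all_compartments(self, params):
        s = healthy_steady_state(params)
        s.trauma = 10.0
        d = inflammation_rhs(s, params)
        for comp in ("blood", "lung", "tissue"):
            assert d[f"mo_a_{comp}"] > 0.0
            assert d[f"nu_a_{comp}"] > 0.0
        assert d.ecl_a > 0.0 and d.ect_a > 0.0  # ECs on both barriers

    def test_il10_inhibits_inos_production(self, params):
        s = healthy_steady_state(params)
        s.mo_a_blood = 50.0
        base = inflammation_rhs(s, params).inos
        s.il10_blood = 5000.0  # saturating IL-10
        inhibited = inflammation_rhs(s, params).inos
        assert inhibited < base

    def test_procoag_coupling_promotes_activation(self, params):
        s = healthy_steady_state(params)
        base = inflammation_rhs(s, params, coupling={"procoag_active": 0.0}).mo_a_blood
        driven = inflammation_rhs(s, params, coupling={"procoag_active": 1.0}).mo_a_blood
        assert driven > base

    def test_negative_state_rejected(self, params):
        s = healthy_steady_state(params)
        s.tnf_blood = -1.0
        with pytest.raises(ValueError):
            inflammation_rhs(s, params)

    def test_damage_does_not_feed_back(self, params):
        """Zeroing (or inflating) the damage integral changes no other
        derivative: damage/death are pure observables."""
        s = healthy_steady_state(params)
        s.trauma = 30.0
        s.il6_blood = 500.0
        p = params.namespace()
        d0 = rhs_vector(0.0, s.vector, p)
        y2 = s.vector.copy()
        y2[IDX["auc_damage"]] = 1e4
        d1 = rhs_vector(0.0, y2, p)
        mask = np.arange(N_STATES) != IDX["auc_damage"]
        assert np.array_equal(d0[mask], d1[mask])


class TestMigrationTopology:
    def test_no_flux_without_active_cells(self, params):
        fluxes = migration_fluxes(healthy_steady_state(params), params)
        for pop in fluxes.values():
            assert all(v == 0.0 for v in pop.values())

    def test_only_blood_to_periphery(self, params):
        s = healthy_steady_state(params)
        s.mo_a_blood = 40.0
        s.nu_a_blood = 100.0
        s.mo_a_lung = 30.0  # peripheral pools never migrate back
        fluxes = migration_fluxes(s, params)
        for pop in fluxes.values():
            assert pop["lung_to_blood"] == 0.0
            assert pop["tissue_to_blood"] == 0.0
            assert pop["lung_to_tissue"] == 0.0

    def test_blood_efflux_conserved(self, params):
        s = healthy_steady_state(params)
        s.mo_a_blood = 40.0
        s.nu_a_blood = 100.0
        p = params.namespace()
        fluxes = migration_fluxes(s, params)
        for pop, pool in (("Mo_active", 40.0), ("Nu_active", 100.0)):
            efflux = (p.k_mig_lung + p.k_mig_tissue) * pool
            assert fluxes[pop]["blood_to_lung"] + fluxes[pop]["blood_to_tissue"] == pytest.approx(
                efflux, rel=1e-12
            )


class TestIntegration:
    def test_empty_scenario_preserves_steady_state(self, params):
        scen = Scenario(t_initial=0.0, horizon=360.0)
        traj = integrate_scenario(scen, params)
        f = traj.frame
        ref = healthy_steady_state(params).vector
        scale = np.maximum(np.abs(ref), 1.0)
        dev = np.abs(f[list(STATE_NAMES)].to_numpy() - ref) / scale
        assert dev.max() < 1e-6
        assert f["damage"].max() == 0.0
        assert traj.time_of_death is None

    def test_trajectory_invariants(self, porcine_trajectory):
        f = porcine_trajectory.frame
        assert (np.diff(f["auc_damage"]) >= -1e-9).all()
        assert (np.diff(f["bled"]) >= -1e-9).all()
        assert (np.diff(f["infused"]) >= -1e-9).all()
        assert (f[list(STATE_NAMES)].to_numpy() >= -1e-9).all()
        assert f["O2Sat_pct"].max() <= 98.0 + 1e-9

    def test_volume_mass_balance(self, porcine_trajectory):
        f = porcine_trajectory.frame
        v0 = f["volume"].iloc[0]
        reconstructed = v0 - f["bled"] + f["infused"]
        rel = np.abs(f["volume"] - reconstructed) / v0
        assert rel.max() < 1e-3

    def test_constant_damage_death_time_analytic(self, constant_damage_run):
        assert constant_damage_run.time_of_death == pytest.approx(DEATH_THRESHOLD, abs=0.01)
        # death latched, integration continues to the horizon
        assert constant_damage_run.frame["time_min"].iloc[-1] == pytest.approx(360.0)
        assert constant_damage_run.last_time_alive() == pytest.approx(DEATH_THRESHOLD, abs=0.01)

    @pytest.mark.parametrize("rate", [0.5, 1.0, 5.0])
    def test_death_time_scales_inversely_with_rate(self, params, rate):
        p = make_constant_damage_params(params, rate=rate)
        traj = integrate_scenario(make_constant_damage_scenario(horizon=600.0), p)
        assert traj.time_of_death == pytest.approx(DEATH_THRESHOLD / rate, abs=0.05)

    def test_solver_convergence(self, params, porcine_scenario):
        """Tightening tolerances barely moves the observables."""
        p = make_constant_damage_params(params, rate=1.0)
        scen = make_constant_damage_scenario()
        loose = integrate_scenario(scen, p, SolverOptions(rtol=1e-6, atol=1e-9))
        tight = integrate_scenario(scen, p, SolverOptions(rtol=1e-9, atol=1e-12))
        assert abs(loose.time_of_death - tight.time_of_death) < 0.05

    def test_exported_columns_and_roundtrip(self, porcine_trajectory, tmp_path):
        path = tmp_path / "traj.csv"
        porcine_trajectory.to_csv(path)
        f = pd.read_csv(path)
        required = {"time_min", "BP_mmHg", "O2Sat_pct", "bp_damage", "o2sat_damage",
                    "il6_damage", "trauma_damage", "damage", "auc_damage", "bled_mL",
                    "infused_mL", "EPAL", "death_flag", *STATE_NAMES}
        assert required <= set(f.columns)
        assert np.allclose(f["damage"], f[["bp_damage", "o2sat_damage", "il6_damage",
                                           "trauma_damage"]].sum(axis=1), atol=1e-6)

    def test_vasopressor_window_raises_pressure_then_washes_out(self, params):
        from hemotwin.scenarios import VasopressorOrder

        base = Scenario(t_initial=0.0, horizon=120.0,
                        injuries=[InjuryEvent(time=0.0, iss=20)])
        dosed = Scenario(t_initial=0.0, horizon=120.0,
                         injuries=[InjuryEvent(time=0.0, iss=20)],
                         vasopressors=[VasopressorOrder(start=10.0, duration=20.0,
                                                        dose_rate=5.0)])
        t_ref = integrate_scenario(base, params)
        t_dose = integrate_scenario(dosed, params)
        grid = np.linspace(15.0, 30.0, 10)
        bp_ref = np.interp(grid, t_ref.times, t_ref.frame["BP_mmHg"])
        bp_dose = np.interp(grid, t_dose.times, t_dose.frame["BP_mmHg"])
        assert (bp_dose > bp_ref).all()
        # washout: effect fades well after the window
        end_ref = float(t_ref.frame["BP_mmHg"].iloc[-1])
        end_dose = float(t_dose.frame["BP_mmHg"].iloc[-1])
        assert abs(end_dose - end_ref) < 0.1 * abs(
            np.max(bp_dose - bp_ref)
        ) + 1e-6

    def test_equal_volume_plasma_beats_crystalloid_on_hemostasis(self, params):
        """Paired scenarios differing only in infusion product: plasma
        yields at least as much clot and no more cumulative bleeding than
        an equal-volume crystalloid infusion."""
        from hemotwin.scenarios import InfusionOrder

        runs = {}
        for product in ("plasma", "crystalloid"):
            scen = Scenario(
                t_initial=-30.0,
                horizon=360.0,
                injuries=[InjuryEvent(time=-30.0, iss=40)],
                infusions=[InfusionOrder(product, start=30.0, volume=1000.0, duration=30.0)],
                blood_volume_initial=5000.0,
                species="human",
            )
            runs[product] = integrate_scenario(scen, params)
        t = np.linspace(60.0, 360.0, 50)
        clot_plasma = np.interp(t, runs["plasma"].times, runs["plasma"].frame["clot"])
        clot_cryst = np.interp(t, runs["crystalloid"].times, runs["crystalloid"].frame["clot"])
        assert (clot_plasma >= clot_cryst - 1e-9).all()
        assert runs["plasma"].bled_volume <= runs["crystalloid"].bled_volume

    def test_death_readout_consistent_with_exported_auc(self, constant_damage_run, params):
        """Last time alive agrees with the first threshold crossing
        recomputed from the exported AUC series."""
        f = constant_damage_run.frame
        crossing = np.interp(DEATH_THRESHOLD, f["auc_damage"], f["time_min"])
        assert constant_damage_run.last_time_alive() == pytest.approx(crossing, abs=0.05)
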