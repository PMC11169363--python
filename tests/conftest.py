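"""Shared fixtures: default parameters, reference scenarios, and the heavy
session-scoped runs (virtual arms, parameter recovery) reused across tests."""

import numpy as np
import pytest

from hemotwin import (
    ParameterSet,
    Scenario,
    InjuryEvent,
    build_porcine_scenario,
    integrate_scenario,
)


@pytest.fixture(scope="session")
def params():
    return ParameterSet.default()


@pytest.fixture(scope="session")
def porcine_scenario():
    return build_porcine_scenario("plasma_rbc", estimated_blood_volume=2000.0)


@pytest.fixture(scope="session")
def porcine_trajectory(porcine_scenario, params):
    return integrate_scenario(porcine_scenario, params)


def make_constant_damage_params(params, rate=1.0):
    """Parameters freezing every dynamic channel so the composite damage
    rate is exactly ``rate``/min once trauma is set to 75·rate (all other
    damage components stay zero)."""
    return params.with_updates(
        {
            "core.k_act_scale": 0.0,  # no cell/EC activation -> no cytokines
            "core.k_trauma_decay": 0.0,  # trauma holds its value
            "hemo.k_bleed": 0.0,  # no bleeding -> BP at baseline
            "core.k_damp": 0.0,
            "damage.k_damage_trauma": rate,
        }
    )


def make_constant_damage_scenario(horizon=360.0):
    """Scenario driving trauma to 75 at t=0 (with frozen dynamics this holds
    the damage rate at k_damage_trauma per minute)."""
    return Scenario(
        t_initial=0.0,
        horizon=horizon,
        injuries=[InjuryEvent(time=0.0, iss=75)],
    )


@pytest.fixture(scope="session")
def constant_damage_run(params):
    p = make_constant_damage_params(params, rate=1.0)
    scen = make_constant_damage_scenario(horizon=360.0)
    return integrate_scenario(scen, p)


@pytest.fixture(scope="session")
def seven_arm_summary(params):
    """Full-size virtual porcine trial: 7 arms × 100 members."""
    from hemotwin import run_porcine_arms
    from hemotwin.model_core import SolverOptions

    return run_porcine_arms(
        seed=12345,
        n_members=100,
        params=params,
        solver=SolverOptions(rtol=1e-5, atol=1e-8, dt_out=2.0),
    )


@pytest.fixture(scope="session")
def recovery_fit():
    """Parameter-recovery experiment: 6-subject synthetic porcine cohort at
    5% observation noise, refit with the blocked SMC at a reduced particle
    budget.  Returns (cohort, fit result)."""
    from hemotwin import FitConfig, Subject, default_weights, gen_porcine_cohort, smc_fit
    from hemotwin.model_core import SolverOptions

    base = ParameterSet.default()
    solver = SolverOptions(rtol=1e-5, atol=1e-8, dt_out=2.0)
    cohort = gen_porcine_cohort(6, seed=2024, noise=0.05, params=base, solver=solver)
    subjects = [
        Subject(id=s.id, scenario=s.scenario, observations=default_weights(s.observations))
        for s in cohort.subjects
    ]
    cfg = FitConfig(
        priors=dict(base.local_ranges),
        global_names=[],
        local_names=sorted(base.local_ranges),
        n_particles=28,
        n_generations=6,
        seed=99,
        solver=solver,
    )
    result = smc_fit(subjects, cfg)
    return cohort, result


@pytest.fixture(scope="session")
def human_recovery_fit():
    """Human-stage recovery: sparse synthetic records (admission O2Sat and
    platelets, ≤4 MAP points, outcome) refit per subject with globals
    locked at truth; the outcome enters the objective, as in the human
    calibration stage.  Returns (cohort, {subject id: fitted locals})."""
    from hemotwin import FitConfig, Subject, default_weights, gen_human_cohort, smc_fit
    from hemotwin.model_core import SolverOptions

    base = ParameterSet.default()
    solver = SolverOptions(rtol=1e-5, atol=1e-8, dt_out=2.0)
    cohort = gen_human_cohort(6, seed=404, mortality_fraction=0.5, params=base, solver=solver)
    fitted = {}
    for i, s in enumerate(cohort.subjects):
        subj = Subject(id=s.id, scenario=s.scenario,
                       observations=default_weights(s.observations))
        cfg = FitConfig(
            priors=dict(base.local_ranges),
            global_names=[],
            local_names=sorted(base.local_ranges),
            n_particles=20,
            n_generations=5,
            seed=500 + i,
            solver=solver,
        )
        fitted[s.id] = smc_fit([subj], cfg).local_estimates[s.id]
    return cohort, fitted
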