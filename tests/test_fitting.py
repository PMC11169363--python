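"""Tests of the calibration objective, physiologic heuristics, the blocked
sequential Monte Carlo sampler, and the verification protocols."""

import numpy as np
import pandas as pd
import pytest

from hemotwin import (
    FitConfig,
    HeuristicConstraints,
    ParameterSet,
    Subject,
    default_weights,
    half_fit_half_predict,
    heuristic_penalty,
    retune_human_globals,
    smc_fit,
    weighted_ssq,
)
from hemotwin.fitting import HUMAN_FIT_ANALYTES, _evaluate_subject
from hemotwin.model_core import SolverOptions, Trajectory


def make_flat_trajectory(horizon=360.0, time_of_death=None, **columns):
    """A synthetic trajectory frame with constant (or supplied) columns —
    a stand-in for an integrated run when only the table shape matters."""
    t = np.linspace(0.0, horizon, 200)
    defaults = dict(
        tnf_blood=50.0, il1_blood=20.0, il6_blood=100.0, il10_blood=30.0,
        BP_mmHg=85.0, O2Sat_pct=97.0, no=12.0, platelets=250.0, rbc=0.9,
        bled=2000.0, auc_damage=np.linspace(0, 50.0, 200),
        procoag_i=0.8, procoag_a=0.05, anticoag_i=0.8, anticoag_a=0.05,
        mo_r_blood=500.0, mo_a_blood=10.0, nu_r_blood=4000.0, nu_a_blood=50.0,
        ecl_a=0.1,
    )
    defaults.update(columns)
    frame = pd.DataFrame({"time_min": t})
    for name, val in defaults.items():
        frame[name] = val
    frame["Mo"] = frame["mo_r_blood"] + frame["mo_a_blood"]
    frame["Nu"] = frame["nu_r_blood"] + frame["nu_a_blood"]
    frame["pro_coag_avg"] = 100 * (frame["procoag_i"] + frame["procoag_a"])
    frame["anti_coag_avg"] = 100 * (frame["anticoag_i"] + frame["anticoag_a"])
    frame["EPAL"] = frame["ecl_a"]
    return Trajectory.from_frame(frame, time_of_death=time_of_death)


class TestWeightedSSQ:
    def test_perfect_fit_scores_zero(self):
        traj = make_flat_trajectory(BP_mmHg=85.0)
        obs = pd.DataFrame(
            [{"analyte": "BP", "time_min": t, "value": 85.0, "weight": 2.0} for t in (10, 50)]
        )
        assert weighted_ssq(traj, obs) == 0.0

    def test_single_residual(self):
        traj = make_flat_trajectory(BP_mmHg=85.0)
        obs = pd.DataFrame([{"analyte": "BP", "time_min": 30.0, "value": 83.0, "weight": 3.0}])
        assert weighted_ssq(traj, obs) == pytest.approx(12.0)  # 3 * 2^2

    def test_row_order_invariant(self):
        traj = make_flat_trajectory()
        rows = [
            {"analyte": "BP", "time_min": 30.0, "value": 80.0, "weight": 1.0},
            {"analyte": "platelets", "time_min": 10.0, "value": 200.0, "weight": 0.5},
            {"analyte": "O2Sat", "time_min": 0.0, "value": 95.0, "weight": 2.0},
        ]
        a = weighted_ssq(traj, pd.DataFrame(rows))
        b = weighted_ssq(traj, pd.DataFrame(rows[::-1]))
        assert a == pytest.approx(b, rel=1e-12)

    def test_unknown_analyte_rejected(self):
        with pytest.raises(KeyError):
            weighted_ssq(
                make_flat_trajectory(),
                pd.DataFrame([{"analyte": "CRP", "time_min": 0.0, "value": 1.0, "weight": 1.0}]),
            )

    def test_death_time_residual_two_sided(self):
        traj = make_flat_trajectory(time_of_death=200.0)
        obs = pd.DataFrame(
            [{"analyte": "time_of_death", "time_min": 210.0, "value": 210.0, "weight": 1.0}]
        )
        assert weighted_ssq(traj, obs) == pytest.approx(100.0)

    def test_survivor_penalized_only_for_early_model_death(self):
        obs = pd.DataFrame(
            [{"analyte": "survival_to", "time_min": 360.0, "value": 360.0, "weight": 1.0}]
        )
        survivor = make_flat_trajectory(time_of_death=None)
        assert weighted_ssq(survivor, obs) == 0.0
        # early death: quadratic residual plus the fixed label penalty that
        # forces "no death event before the survivor's horizon"
        early_death = make_flat_trajectory(time_of_death=300.0)
        assert weighted_ssq(early_death, obs) == pytest.approx(3600.0 + 100.0)
        # a death a fraction of a minute before the horizon still pays the label cost
        boundary = make_flat_trajectory(time_of_death=359.9)
        assert weighted_ssq(boundary, obs) > 100.0

    def test_default_weights_inverse_variance(self):
        obs = pd.DataFrame(
            [
                {"analyte": "BP", "time_min": 0.0, "value": 60.0, "weight": 1.0},
                {"analyte": "BP", "time_min": 10.0, "value": 100.0, "weight": 1.0},
                {"analyte": "platelets", "time_min": 0.0, "value": 200.0, "weight": 1.0},
                {"analyte": "survival_to", "time_min": 360.0, "value": 360.0, "weight": 1.0},
            ]
        )
        w = default_weights(obs)
        # informative spread -> true inverse variance
        assert w.loc[w["analyte"] == "BP", "weight"].iloc[0] == pytest.approx(1.0 / 400.0)
        # singleton -> floored at (10% of level)^2
        assert w.loc[w["analyte"] == "platelets", "weight"].iloc[0] == pytest.approx(1.0 / 400.0)
        # outcome records carry the fixed 5-minute residual scale
        assert w.loc[w["analyte"] == "survival_to", "weight"].iloc[0] == pytest.approx(1.0 / 25.0)


class TestHeuristicPenalty:
    def test_within_bounds_scores_zero(self):
        traj = make_flat_trajectory()
        assert heuristic_penalty(traj, healthy_blood_volume=5000.0) == 0.0

    def test_cytokine_peak_violation(self):
        traj = make_flat_trajectory(tnf_blood=12_000.0)
        assert heuristic_penalty(traj) > 0.0

    def test_insufficient_bleed_violation(self):
        traj = make_flat_trajectory(bled=1000.0)  # 20% of 5 L
        assert heuristic_penalty(traj, healthy_blood_volume=5000.0) > 0.0

    def test_bp_and_no_bounds(self):
        assert heuristic_penalty(make_flat_trajectory(BP_mmHg=15.0)) > 0.0
        assert heuristic_penalty(make_flat_trajectory(BP_mmHg=260.0)) > 0.0
        assert heuristic_penalty(make_flat_trajectory(no=1200.0)) > 0.0

    def test_assessment_window_stops_at_death(self):
        """A bound violated only after death does not count."""
        t = np.linspace(0, 360, 200)
        tnf = np.where(t < 100.0, 500.0, 20_000.0)
        traj = make_flat_trajectory(tnf_blood=tnf, time_of_death=90.0)
        assert heuristic_penalty(traj) == 0.0

    def test_penalty_increases_with_violation(self):
        p1 = heuristic_penalty(make_flat_trajectory(tnf_blood=12_000.0))
        p2 = heuristic_penalty(make_flat_trajectory(tnf_blood=30_000.0))
        assert p2 > p1 > 0.0

    def test_invalid_constraints_rejected(self):
        with pytest.raises(ValueError):
            HeuristicConstraints(bp_min=0.0)


@pytest.fixture(scope="module")
def tiny_subjects():
    """Two fast synthetic porcine subjects for sampler-behavior tests."""
    from hemotwin import gen_porcine_cohort

    solver = SolverOptions(rtol=1e-4, atol=1e-7, dt_out=5.0)
    cohort = gen_porcine_cohort(2, seed=5, noise=0.05, solver=solver)
    return [
        Subject(id=s.id, scenario=s.scenario, observations=default_weights(s.observations))
        for s in cohort.subjects
    ], solver


def _tiny_config(seed=3, **kw):
    base = ParameterSet.default()
    defaults = dict(
        priors={"hemo.k_bleed": (30.0, 90.0), "cyto.k_il6_scale": (0.5, 2.0)},
        global_names=[],
        local_names=["hemo.k_bleed", "cyto.k_il6_scale"],
        n_particles=8,
        n_generations=3,
        seed=seed,
    )
    defaults.update(kw)
    return FitConfig(**defaults)


class TestSMC:
    def test_seeded_determinism(self, tiny_subjects):
        subjects, solver = tiny_subjects
        cfg = _tiny_config(solver=solver)
        a = smc_fit(subjects, cfg)
        b = smc_fit(subjects, _tiny_config(solver=solver))
        assert a.global_estimates == b.global_estimates
        assert a.local_estimates == b.local_estimates
        assert a.best_score_history == b.best_score_history

    def test_best_objective_monotone_nonincreasing(self, tiny_subjects):
        subjects, solver = tiny_subjects
        res = smc_fit(subjects, _tiny_config(solver=solver))
        hist = res.best_score_history
        assert all(b <= a + 1e-12 for a, b in zip(hist, hist[1:]))

    def test_total_score_decomposes_over_subjects(self, tiny_subjects):
        subjects, solver = tiny_subjects
        res = smc_fit(subjects, _tiny_config(solver=solver))
        assert res.total_score == pytest.approx(sum(res.subject_scores.values()), rel=1e-9)

    def test_score_reproducible_from_stored_parameters(self, tiny_subjects):
        subjects, solver = tiny_subjects
        cfg = _tiny_config(solver=solver)
        res = smc_fit(subjects, cfg)
        for subj in subjects:
            params = ParameterSet.default().with_updates(res.local_estimates[subj.id])
            ssq, pen = _evaluate_subject(subj, params, cfg)
            assert ssq + pen == pytest.approx(res.subject_scores[subj.id], rel=1e-6)

    def test_empty_subjects_rejected(self):
        with pytest.raises(ValueError):
            smc_fit([], _tiny_config())


class TestVerification:
    def test_empty_holdout_gives_empty_result(self):
        out = half_fit_half_predict({"cyto.k_tnf": 0.3}, [], {"hemo.k_bleed": (30.0, 90.0)})
        assert out == {}

    def test_globals_locked_and_locals_in_range(self, tiny_subjects):
        subjects, solver = tiny_subjects
        ranges = {"hemo.k_bleed": (30.0, 90.0), "cyto.k_il6_scale": (0.5, 2.0)}
        locked = {"cyto.k_tnf": 0.31}
        cfg = _tiny_config(solver=solver, n_particles=6, n_generations=2)
        out = half_fit_half_predict(locked, subjects[:1], ranges, cfg)
        (res,) = out.values()
        assert res["globals_locked"] == locked
        for name, value in res["locals"].items():
            lo, hi = ranges[name]
            assert lo <= value <= hi


class TestHumanRetuning:
    def test_only_no_and_damage_globals_may_open(self, tiny_subjects):
        subjects, solver = tiny_subjects
        cfg = FitConfig(
            priors={"cyto.k_tnf": (0.1, 0.5)},
            global_names=["cyto.k_tnf"],  # porcine global: must be rejected
            local_names=[],
            n_particles=4,
            n_generations=2,
            solver=solver,
        )
        with pytest.raises(ValueError, match="may not be opened"):
            retune_human_globals(ParameterSet.default(), subjects, cfg)

    def test_human_objective_restricted_to_fit_targets(self):
        assert set(HUMAN_FIT_ANALYTES) == {"O2Sat", "BP", "platelets",
                                           "time_of_death", "survival_to"}

    def test_retuned_globals_stay_in_allowed_set(self, tiny_subjects):
        subjects, solver = tiny_subjects
        cfg = FitConfig(
            priors={"no.K_no_ma": (0.0, 0.05), "damage.k_damage_trauma": (0.5, 2.0)},
            global_names=["no.K_no_ma", "damage.k_damage_trauma"],
            local_names=[],
            n_particles=6,
            n_generations=2,
            seed=1,
            solver=solver,
        )
        base = ParameterSet.default()
        updated, result = retune_human_globals(base, subjects, cfg)
        moved = {k for k in updated.keys() if updated[k] != base[k]}
        assert moved <= {"no.K_no_ma", "damage.k_damage_trauma"}
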