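"""Weighted least-squares calibration by sequential Monte Carlo.

The objective per subject is a weighted sum of squared residuals over sparse
analyte observations, plus quadratic-hinge penalties for physiologic
heuristics (cytokine peaks, BP range, NO ceiling, minimum blood loss).
Parameters split into globals shared by every subject and per-subject
locals.  The optimizer is a seeded sequential Monte Carlo over the joint
(globals ⊕ locals) space with adaptive Boltzmann selection, systematic
resampling, and a shrinking Gaussian perturbation kernel.  Because the total
objective decomposes as a sum of per-subject scores and each subject's
locals touch only its own score, local blocks are reselected per subject
while globals are selected on the total — a blocked-resampling scheme that
greatly improves recovery at small particle counts.

Verification follows the half-fit-half-predict protocol: globals locked,
locals refit on holdout subjects over the training-stage ranges.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import damage_death
from .model_core import ANALYTE_COLUMNS, SolverOptions, Trajectory, integrate_scenario
from .parameters import NOParams, ParameterSet
from .scenarios import Scenario

#: analytes the human calibration stage fits (plus time-of-death records)
HUMAN_FIT_ANALYTES = ("O2Sat", "BP", "platelets", "time_of_death", "survival_to")
#: globals that may be re-tuned on human data: the NO pathway and the
#: damage/death outcome constants (everything else stays locked from the
#: porcine stage)
HUMAN_RETUNABLE_GLOBALS = tuple(NOParams.KEYS) + (
    "damage.k_damage_bp",
    "damage.x_damage_bp",
    "damage.bp_damage_thresh",
    "damage.k_damage_o2sat",
    "damage.o2sat_damage_thresh",
    "damage.k_damage_il6",
    "damage.x_damage_il6",
    "damage.il6_damage_thresh",
    "damage.k_damage_trauma",
    "death.death_threshold",
)


@dataclass
class Subject:
    """One calibration subject: a scenario plus its observation table.

    Observations: DataFrame with columns analyte, time_min, value, weight.
    Two outcome pseudo-analytes are supported: ``time_of_death`` (value =
    observed death time, two-sided residual in minutes) and ``survival_to``
    (value = last time alive; one-sided — penalized only if the model kills
    the subject earlier).
    """

    id: str
    scenario: Scenario
    observations: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"analyte", "time_min", "value", "weight"}
        if not required <= set(self.observations.columns):
            raise ValueError(f"observations must have columns {sorted(required)}")
        if (self.observations["weight"] <= 0).any():
            raise ValueError("observation weights must be > 0")


#: residual scale (min) for outcome records: a 5-minute miss on the death /
#: last-alive time costs one objective unit
OUTCOME_TIME_SCALE_MIN = 5.0
#: fixed objective cost for killing a subject whose record says survivor
SURVIVOR_DEATH_PENALTY = 100.0


def default_weights(observations: pd.DataFrame) -> pd.DataFrame:
    """Per-subject, per-analyte inverse-variance weights (scale-free
    residuals), floored at (10% of the analyte's mean level)² so that
    sparse analytes with few near-identical points cannot acquire divergent
    weight.  Outcome pseudo-analytes (``time_of_death``/``survival_to``)
    are event times, not repeated measures, and get a fixed 5-minute
    residual scale instead."""
    obs = observations.reset_index(drop=True).copy()
    w = np.ones(len(obs))
    for analyte, grp in obs.groupby("analyte"):
        if analyte in ("time_of_death", "survival_to"):
            w[grp.index.to_numpy()] = 1.0 / OUTCOME_TIME_SCALE_MIN**2
            continue
        v = grp["value"].to_numpy(float)
        var = float(np.var(v)) if len(v) > 1 else 0.0
        scale = float(np.mean(np.abs(v))) if np.any(v) else 1.0
        var = max(var, (0.1 * scale) ** 2, 1e-12)
        w[grp.index.to_numpy()] = 1.0 / var
    obs["weight"] = w
    return obs


def weighted_ssq(trajectory: Trajectory, observations: pd.DataFrame) -> float:
    """Weighted least-squares score Σ w·(model − obs)² over the observation
    table.  Analyte names must map to exported trajectory columns."""
    score = 0.0
    lta_model = None
    for analyte, grp in observations.groupby("analyte"):
        w = grp["weight"].to_numpy(float)
        v = grp["value"].to_numpy(float)
        if analyte in ("time_of_death", "survival_to"):
            if lta_model is None:
                lta_model = trajectory.last_time_alive()
            if analyte == "time_of_death":
                score += float(np.sum(w * (lta_model - v) ** 2))
            else:
                # survivor record: forces no death event before its horizon.
                # A fixed label penalty keeps the constraint binding even for
                # deaths a fraction of a minute before the horizon, where the
                # quadratic term alone is vanishingly small.
                early = np.maximum(v - lta_model, 0.0)
                score += float(np.sum(w * early**2))
                score += SURVIVOR_DEATH_PENALTY * float(np.count_nonzero(early > 1e-9))
            continue
        if analyte not in ANALYTE_COLUMNS:
            raise KeyError(f"unknown analyte {analyte!r}")
        model = trajectory.value(analyte, grp["time_min"].to_numpy(float))
        score += float(np.sum(w * (model - v) ** 2))
    return score


@dataclass(frozen=True)
class HeuristicConstraints:
    """Physiologic plausibility bounds assessed until death or the 6-hour
    cut-off.  Violations incur quadratic-hinge penalties."""

    cytokine_peak_max: float = 10_000.0  # pg/mL, applies to TNF/IL-1/IL-6/IL-10
    bp_min: float = 20.0  # mmHg
    bp_max: float = 250.0  # mmHg
    no_max: float = 1000.0  # umol/L
    min_bleed_fraction: float = 0.30  # of healthy blood volume
    il1_peak_max: float = 5_000.0  # porcine-stage physiologic range
    il10_peak_max: float = 5_000.0
    penalty_scale: float = 1e4

    def __post_init__(self) -> None:
        for name, v in asdict(self).items():
            if v <= 0:
                raise ValueError(f"HeuristicConstraints.{name} must be > 0")


def heuristic_penalty(
    trajectory: Trajectory,
    constraints: Optional[HeuristicConstraints] = None,
    healthy_blood_volume: Optional[float] = None,
) -> float:
    """Penalty ≥ 0; exactly 0 iff every bound holds over the assessment
    window (up to death or 360 min), increasing quadratically in relative
    violation magnitude."""
    c = constraints or HeuristicConstraints()
    t_end = min(trajectory.horizon, 360.0)
    if trajectory.time_of_death is not None:
        t_end = min(t_end, trajectory.time_of_death)
    f = trajectory.frame
    mask = f["time_min"].to_numpy() <= t_end + 1e-9

    def hinge_over(value: float, bound: float) -> float:
        return max(value - bound, 0.0) / bound

    def hinge_under(value: float, bound: float) -> float:
        return max(bound - value, 0.0) / bound

    pen = 0.0
    for col, bound in (
        ("tnf_blood", c.cytokine_peak_max),
        ("il6_blood", c.cytokine_peak_max),
        ("il1_blood", min(c.cytokine_peak_max, c.il1_peak_max)),
        ("il10_blood", min(c.cytokine_peak_max, c.il10_peak_max)),
    ):
        pen += hinge_over(float(f.loc[mask, col].max()), bound) ** 2
    pen += hinge_under(float(f.loc[mask, "BP_mmHg"].min()), c.bp_min) ** 2
    pen += hinge_over(float(f.loc[mask, "BP_mmHg"].max()), c.bp_max) ** 2
    pen += hinge_over(float(f.loc[mask, "no"].max()), c.no_max) ** 2
    if healthy_blood_volume is not None:
        bled_end = float(f.loc[mask, "bled"].iloc[-1])
        target = c.min_bleed_fraction * healthy_blood_volume
        pen += hinge_under(bled_end, target) ** 2
    return c.penalty_scale * pen


# ---------------------------------------------------------------------------
# Sequential Monte Carlo
# ---------------------------------------------------------------------------

@dataclass
class FitConfig:
    """SMC configuration: bounded-uniform priors and sampler controls."""

    priors: Dict[str, Tuple[float, float]]
    global_names: Sequence[str]
    local_names: Sequence[str]
    n_particles: int = 64
    n_generations: int = 10
    seed: int = 0
    kernel_scale: float = 0.3  # initial perturbation, fraction of prior width
    kernel_decay: float = 0.85  # per-generation kernel shrinkage
    ess_floor: float = 0.5  # resample diagnostic threshold (fraction of N)
    use_heuristics: bool = True
    fit_analytes: Optional[Sequence[str]] = None  # None = all observed
    solver: SolverOptions = field(default_factory=SolverOptions)

    def __post_init__(self) -> None:
        for name in list(self.global_names) + list(self.local_names):
            if name not in self.priors:
                raise ValueError(f"no prior for fitted parameter {name}")
        for name, (lo, hi) in self.priors.items():
            if not lo < hi:
                raise ValueError(f"degenerate prior for {name}")


@dataclass
class FitResult:
    """Calibration output: locked globals, per-subject locals, audit trail."""

    global_estimates: Dict[str, float]
    local_estimates: Dict[str, Dict[str, float]]  # subject id -> name -> value
    subject_scores: Dict[str, float]
    total_score: float
    best_score_history: List[float]
    heuristic_audit: Dict[str, float]  # subject id -> penalty at the optimum
    ess_history: List[float]
    resample_events: List[int]
    seed: int = 0

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "FitResult":
        with open(path) as fh:
            return cls(**json.load(fh))


def _evaluate_subject(
    subject: Subject, params: ParameterSet, config: FitConfig
) -> Tuple[float, float]:
    """(weighted SSQ, heuristic penalty) for one subject under ``params``."""
    obs = subject.observations
    if config.fit_analytes is not None:
        obs = obs[obs["analyte"].isin(config.fit_analytes)]
    try:
        traj = integrate_scenario(subject.scenario, params, config.solver)
    except RuntimeError:
        return 1e12, 1e12  # solver failure: reject the particle
    ssq = weighted_ssq(traj, obs)
    pen = 0.0
    if config.use_heuristics:
        v0 = subject.scenario.blood_volume_initial or params["hemo.blood_volume_initial"]
        pen = heuristic_penalty(traj, healthy_blood_volume=v0)
    return ssq, pen


def _systematic_resample(weights: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    n = len(weights)
    positions = (rng.random() + np.arange(n)) / n
    return np.searchsorted(np.cumsum(weights), positions).clip(0, n - 1)


def smc_fit(subjects: Sequence[Subject], config: FitConfig) -> FitResult:
    """Joint global/local calibration over all subjects.

    Minimizes Σ_subjects (weighted_ssq + heuristic_penalty).  The running
    best particle's total objective is non-increasing across generations,
    and identical configuration + seed reproduce the result bit-for-bit.
    """
    if not subjects:
        raise ValueError("at least one subject is required")
    rng = np.random.default_rng(config.seed)
    base = ParameterSet.default() if not hasattr(config, "_base") else config._base
    g_names = list(config.global_names)
    l_names = list(config.local_names)
    n_sub = len(subjects)
    N = config.n_particles

    def sample_prior(names: Sequence[str], size: int) -> np.ndarray:
        cols = []
        for name in names:
            lo, hi = config.priors[name]
            cols.append(rng.uniform(lo, hi, size))
        return np.column_stack(cols) if cols else np.zeros((size, 0))

    G = sample_prior(g_names, N)  # (N, n_glob)
    L = np.stack([sample_prior(l_names, N) for _ in range(n_sub)], axis=1)  # (N, n_sub, n_loc)

    def assemble(gi: np.ndarray, li: np.ndarray) -> ParameterSet:
        upd = {k: v for k, v in zip(g_names, gi)}
        upd.update({k: v for k, v in zip(l_names, li)})
        return base.with_updates(upd)

    def eval_particles() -> np.ndarray:
        S = np.empty((N, n_sub))
        for i in range(N):
            for j, subj in enumerate(subjects):
                ssq, pen = _evaluate_subject(subj, assemble(G[i], L[i, j]), config)
                S[i, j] = ssq + pen
        return S

    best: Optional[Dict] = None
    history: List[float] = []
    ess_hist: List[float] = []
    resamples: List[int] = []
    width = {n: config.priors[n][1] - config.priors[n][0] for n in g_names + l_names}

    for gen in range(config.n_generations):
        S = eval_particles()
        totals = S.sum(axis=1)
        i_best = int(np.argmin(totals))
        if best is None or totals[i_best] < best["total"]:
            best = {
                "total": float(totals[i_best]),
                "G": G[i_best].copy(),
                "L": L[i_best].copy(),
                "S": S[i_best].copy(),
            }
        history.append(best["total"])

        # Boltzmann selection weights, temperature set by the score spread
        def weights_from(scores: np.ndarray) -> np.ndarray:
            s = scores - scores.min()
            spread = np.percentile(s, 75)
            T = max(spread, 1e-12)
            w = np.exp(-s / T)
            return w / w.sum()

        w_tot = weights_from(totals)
        ess = float(1.0 / np.sum(w_tot**2))
        ess_hist.append(ess)
        if ess < config.ess_floor * N:
            resamples.append(gen)

        idx_g = _systematic_resample(w_tot, rng)
        G = G[idx_g]
        # per-subject blocked reselection of locals (decomposable objective)
        newL = np.empty_like(L)
        for j in range(n_sub):
            w_j = weights_from(S[:, j])
            idx_j = _systematic_resample(w_j, rng)
            newL[:, j, :] = L[idx_j, j, :]
        L = newL

        # Gaussian perturbation with reflection at the prior bounds
        k = config.kernel_scale * config.kernel_decay**gen
        for c, name in enumerate(g_names):
            lo, hi = config.priors[name]
            G[:, c] = np.clip(
                np.abs(G[:, c] + rng.normal(0, k * width[name], N) - lo) + lo, lo, hi
            )
        for c, name in enumerate(l_names):
            lo, hi = config.priors[name]
            pert = rng.normal(0, k * width[name], (N, n_sub))
            L[:, :, c] = np.clip(np.abs(L[:, :, c] + pert - lo) + lo, lo, hi)
        # elitism: re-inject the incumbent so refinement continues around it
        G[0] = best["G"]
        L[0] = best["L"]

    # final evaluation pass so the incumbent reflects the last generation
    S = eval_particles()
    totals = S.sum(axis=1)
    i_best = int(np.argmin(totals))
    if totals[i_best] < best["total"]:
        best = {
            "total": float(totals[i_best]),
            "G": G[i_best].copy(),
            "L": L[i_best].copy(),
            "S": S[i_best].copy(),
        }
    history.append(best["total"])

    audit: Dict[str, float] = {}
    scores: Dict[str, float] = {}
    for j, subj in enumerate(subjects):
        ssq, pen = _evaluate_subject(subj, assemble(best["G"], best["L"][j]), config)
        scores[subj.id] = ssq + pen
        audit[subj.id] = pen
    return FitResult(
        global_estimates={k: float(v) for k, v in zip(g_names, best["G"])},
        local_estimates={
            subj.id: {k: float(v) for k, v in zip(l_names, best["L"][j])}
            for j, subj in enumerate(subjects)
        },
        subject_scores=scores,
        total_score=float(sum(scores.values())),
        best_score_history=history,
        heuristic_audit=audit,
        ess_history=ess_hist,
        resample_events=resamples,
        seed=config.seed,
    )


def half_fit_half_predict(
    locked_globals: Mapping[str, float],
    holdout: Sequence[Subject],
    local_ranges: Mapping[str, Tuple[float, float]],
    config: Optional[FitConfig] = None,
    base_params: Optional[ParameterSet] = None,
) -> Dict[str, Dict]:
    """Verification protocol: globals locked, locals refit per holdout
    subject over the training-stage ranges; returns per-subject locals,
    scores, and predicted trajectories.  Empty holdout → empty result."""
    out: Dict[str, Dict] = {}
    if not holdout:
        return out
    base = (base_params or ParameterSet.default()).with_updates(dict(locked_globals))
    for subj in holdout:
        cfg = FitConfig(
            priors=dict(local_ranges),
            global_names=[],
            local_names=list(local_ranges),
            n_particles=config.n_particles if config else 32,
            n_generations=config.n_generations if config else 6,
            seed=(config.seed if config else 0) + zlib.crc32(str(subj.id).encode()) % 10_000,
            use_heuristics=config.use_heuristics if config else True,
            fit_analytes=config.fit_analytes if config else None,
            solver=config.solver if config else SolverOptions(),
        )
        cfg._base = base
        res = smc_fit([subj], cfg)
        assert res.global_estimates == {}, "globals must stay locked in verification"
        locals_j = res.local_estimates[subj.id]
        for name, value in locals_j.items():
            lo, hi = local_ranges[name]
            assert lo <= value <= hi, f"local {name} escaped its training range"
        traj = integrate_scenario(subj.scenario, base.with_updates(locals_j), cfg.solver)
        out[subj.id] = {
            "locals": locals_j,
            "score": res.subject_scores[subj.id],
            "trajectory": traj,
            "globals_locked": dict(locked_globals),
        }
    return out


def retune_human_globals(
    porcine_params: ParameterSet,
    human_subjects: Sequence[Subject],
    config: FitConfig,
) -> Tuple[ParameterSet, FitResult]:
    """Human calibration stage: starting from the porcine-locked parameter
    set, re-open only the NO-pathway globals and the damage/death globals
    (everything else stays locked), fit to O2Sat, BP, platelets, and time of
    death / survival, and return the updated parameter set."""
    forbidden = [g for g in config.global_names if g not in HUMAN_RETUNABLE_GLOBALS]
    if forbidden:
        raise ValueError(
            f"globals {forbidden} may not be opened in the human stage; "
            f"only NO and damage/death parameters are re-tunable"
        )
    cfg = FitConfig(
        priors=config.priors,
        global_names=config.global_names,
        local_names=config.local_names,
        n_particles=config.n_particles,
        n_generations=config.n_generations,
        seed=config.seed,
        kernel_scale=config.kernel_scale,
        kernel_decay=config.kernel_decay,
        use_heuristics=config.use_heuristics,
        fit_analytes=list(HUMAN_FIT_ANALYTES),
        solver=config.solver,
    )
    cfg._base = porcine_params
    result = smc_fit(list(human_subjects), cfg)
    updated = porcine_params.with_updates(result.global_estimates)
    # audit: nothing outside the retunable set may have moved
    for key in updated.keys():
        if key not in HUMAN_RETUNABLE_GLOBALS and key not in result.global_estimates:
            assert updated[key] == porcine_params[key]
    return updated, result
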