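"""Virtual populations and in-silico resuscitation experiments.

Virtual porcine populations are generated by sampling local parameters
uniformly from fitted (or reference) ranges — 100 unique members per arm —
and forward-simulating each member under one of seven protocol arms grouped
by pre-liver-injury treatment:

* group 1 (original crystalloid dilution) — post-injury resuscitation with
  (1a) fluids, (1b) plasma only, or (1c) RBC+plasma;
* group 2 (one plasma unit, ~300 mL, instead of the dilution fluids) —
  (2a) plasma only or (2b) RBC+plasma;
* group 3 (equal-volume plasma, ~1250 mL) — (3a) plasma only or
  (3b) RBC+plasma.

The five human experiments perturb each fitted patient's real infusion
schedule (extra pre-hospital plasma at injury+15 min, or ±10/±30 min shifts
of every infusion) and report per-patient percent changes against that
patient's own baseline run, split by survivor status.  Members share their
random draws across arms (common random numbers), so arm contrasts are
paired.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .model_core import SolverOptions, Trajectory, integrate_scenario
from .parameters import ParameterSet
from .scenarios import Scenario, apply_experiment, build_porcine_scenario

#: the seven virtual porcine arms: (arm id, pre-liver-injury protocol,
#: post-liver-injury resuscitation)
PORCINE_ARM_SPECS: Tuple[Tuple[str, str, str], ...] = (
    ("1a", "fluids", "fluids"),
    ("1b", "fluids", "plasma_only"),
    ("1c", "fluids", "plasma_rbc"),
    ("2a", "one_unit_plasma", "plasma_only"),
    ("2b", "one_unit_plasma", "plasma_rbc"),
    ("3a", "equal_volume_plasma", "plasma_only"),
    ("3b", "equal_volume_plasma", "plasma_rbc"),
)
HUMAN_EXPERIMENTS = ("exp1", "exp2", "exp3", "exp4", "exp5")
DEFAULT_N_MEMBERS = 100
#: resuscitation-volume range observed in fitting (mL); virtual-arm infusion
#: volumes are sampled from this range rather than recomputed per subject
FITTED_RESUS_VOLUME_RANGE = (1000.0, 1400.0)
FITTED_EBV_RANGE = (1800.0, 2200.0)


@dataclass
class PopulationSpec:
    """One virtual porcine arm."""

    arm_id: str
    pre_protocol: str
    post_arm: str
    n_members: int = DEFAULT_N_MEMBERS
    local_ranges: Dict[str, Tuple[float, float]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_members < 1:
            raise ValueError("n_members must be >= 1")
        for k, (lo, hi) in self.local_ranges.items():
            if not lo < hi:
                raise ValueError(f"degenerate range for {k}")


@dataclass
class CohortSummary:
    """Cohort outputs: per-member long table plus mean ± SD summaries."""

    members: pd.DataFrame  # one row per (arm/experiment, member, metric set)
    summary: pd.DataFrame  # one row per (arm/experiment, stratum, metric)
    failures: List[str] = field(default_factory=list)

    def to_csv(self, members_path, summary_path) -> None:
        self.members.to_csv(members_path, index=False)
        self.summary.to_csv(summary_path, index=False)


def sample_local_params(
    ranges: Mapping[str, Tuple[float, float]], n: int, seed: int
) -> List[Dict[str, float]]:
    """Draw ``n`` independent uniform local-parameter sets (seeded)."""
    for k, (lo, hi) in ranges.items():
        if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
            raise ValueError(f"degenerate range for {k}: [{lo}, {hi}]")
    rng = np.random.default_rng(seed)
    keys = sorted(ranges)
    return [
        {k: float(rng.uniform(*ranges[k])) for k in keys}
        for _ in range(n)
    ]


def _member_metrics(traj: Trajectory) -> Dict[str, float]:
    f = traj.frame
    t = f["time_min"].to_numpy()
    post = t >= 0.0  # monitoring window relative to the anchoring injury
    clot = f["clot"].to_numpy()
    span = max(t[post][-1] - t[post][0], 1e-9)
    return {
        "bled_mL": traj.bled_volume,
        "auc_damage": traj.auc_damage,
        "survival_time_min": traj.last_time_alive(),
        "died": int(traj.time_of_death is not None),
        "clot_mean": float(np.trapezoid(clot[post], t[post]) / span),
        "tnf_end": float(f["tnf_blood"].iloc[-1]),
        "il6_end": float(f["il6_blood"].iloc[-1]),
        "il10_end": float(f["il10_blood"].iloc[-1]),
        "platelets_end": float(f["platelets"].iloc[-1]),
    }


def run_porcine_arms(
    local_ranges: Optional[Mapping[str, Tuple[float, float]]] = None,
    seed: int = 0,
    n_members: int = DEFAULT_N_MEMBERS,
    params: Optional[ParameterSet] = None,
    solver: Optional[SolverOptions] = None,
) -> CohortSummary:
    """Simulate the seven virtual porcine arms (``n_members`` each).

    Local-parameter draws, estimated blood volumes, and infusion volumes are
    shared across arms member-by-member (common random numbers), so the arm
    contrasts are paired.  Members whose simulation fails are flagged and
    the summary covers completers.
    """
    base = params or ParameterSet.default()
    ranges = dict(local_ranges or base.local_ranges)
    draws = sample_local_params(ranges, n_members, seed)
    rng = np.random.default_rng(seed + 1)
    ebv = rng.uniform(*FITTED_EBV_RANGE, n_members)
    resus = rng.uniform(*FITTED_RESUS_VOLUME_RANGE, n_members)

    rows: List[Dict] = []
    failures: List[str] = []
    for arm_id, pre, post in PORCINE_ARM_SPECS:
        for m in range(n_members):
            scen = build_porcine_scenario(
                post,
                float(ebv[m]),
                overrides={"pre_protocol": pre, "resus_volume": float(resus[m])},
            )
            try:
                traj = integrate_scenario(scen, base.with_updates(draws[m]), solver)
            except RuntimeError as exc:
                failures.append(f"{arm_id}/member{m}: {exc}")
                continue
            rows.append({"arm": arm_id, "member": m, **_member_metrics(traj)})

    members = pd.DataFrame(rows)
    metrics = [c for c in members.columns if c not in ("arm", "member")]
    summary = (
        members.melt(id_vars=["arm"], value_vars=metrics, var_name="metric")
        .groupby(["arm", "metric"])["value"]
        .agg(n="count", mean="mean", sd="std")
        .reset_index()
    )
    summary.insert(1, "stratum", "all")
    return CohortSummary(members=members, summary=summary, failures=failures)


# ---------------------------------------------------------------------------
# Human in-silico experiments
# ---------------------------------------------------------------------------

@dataclass
class VirtualPatient:
    """A fitted digital twin: scenario, parameters, and baseline run."""

    id: str
    scenario: Scenario
    params: ParameterSet
    baseline: Optional[Trajectory] = None

    def ensure_baseline(self, solver: Optional[SolverOptions] = None) -> Trajectory:
        if self.baseline is None:
            self.baseline = integrate_scenario(self.scenario, self.params, solver)
        return self.baseline


def first_plasma_stats(patients: Sequence[VirtualPatient]) -> Dict[str, float]:
    """Mean volume/duration of each patient's first plasma infusion."""
    vols, durs = [], []
    for pt in patients:
        plasma = [o for o in pt.scenario.infusions if o.product == "plasma"]
        if plasma:
            first = min(plasma, key=lambda o: o.start)
            vols.append(first.volume)
            durs.append(first.duration)
    if not vols:
        raise ValueError("no plasma infusions among the selected patients")
    return {
        "mean_plasma_volume": float(np.mean(vols)),
        "mean_plasma_duration": float(np.mean(durs)),
    }


def run_human_experiments(
    patients: Sequence[VirtualPatient],
    seed: int = 0,
    experiments: Sequence[str] = HUMAN_EXPERIMENTS,
    solver: Optional[SolverOptions] = None,
) -> CohortSummary:
    """Run the five infusion-timing experiments on fitted virtual patients.

    Patients without a plasma infusion are excluded (with reason).  Each
    experiment trajectory shares its patient's parameters and differs only
    in schedule; metrics are per-patient percent changes vs that patient's
    baseline in bled volume, AUC damage, and survival time, stratified by
    baseline survivor status.
    """
    eligible: List[VirtualPatient] = []
    failures: List[str] = []
    for pt in patients:
        if any(o.product == "plasma" for o in pt.scenario.infusions):
            eligible.append(pt)
        else:
            failures.append(f"{pt.id}: excluded, no plasma infusion in schedule")
    if not eligible:
        raise ValueError("no eligible patients (all lack plasma infusions)")
    stats = first_plasma_stats(eligible)

    rows: List[Dict] = []
    for pt in eligible:
        base_traj = pt.ensure_baseline(solver)
        base_m = _member_metrics(base_traj)
        stratum = "non-survivor" if base_m["died"] else "survivor"
        for exp in experiments:
            scen = apply_experiment(pt.scenario, exp, cohort_stats=stats)
            try:
                traj = integrate_scenario(scen, pt.params, solver)
            except RuntimeError as exc:
                failures.append(f"{pt.id}/{exp}: {exc}")
                continue
            m = _member_metrics(traj)

            def pct(key: str) -> float:
                ref = base_m[key]
                return 100.0 * (m[key] - ref) / ref if ref else 0.0

            rows.append(
                {
                    "experiment": exp,
                    "patient": pt.id,
                    "stratum": stratum,
                    "bled_mL": m["bled_mL"],
                    "auc_damage": m["auc_damage"],
                    "survival_time_min": m["survival_time_min"],
                    "died": m["died"],
                    "delta_bled_pct": pct("bled_mL"),
                    "delta_auc_damage_pct": pct("auc_damage"),
                    "delta_survival_pct": pct("survival_time_min"),
                    "delta_survival_min": m["survival_time_min"] - base_m["survival_time_min"],
                }
            )

    members = pd.DataFrame(rows)
    delta_cols = [c for c in members.columns if c.startswith("delta_")]
    pieces = []
    for strat in ("all", "survivor", "non-survivor"):
        sub = members if strat == "all" else members[members["stratum"] == strat]
        if sub.empty:
            continue
        agg = (
            sub.melt(id_vars=["experiment"], value_vars=delta_cols, var_name="metric")
            .groupby(["experiment", "metric"])["value"]
            .agg(n="count", mean="mean", sd="std")
            .reset_index()
        )
        agg.insert(1, "stratum", strat)
        pieces.append(agg)
    summary = pd.concat(pieces, ignore_index=True)
    return CohortSummary(members=members, summary=summary, failures=failures)
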