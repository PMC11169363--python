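"""Ground-truth-known synthetic cohorts for calibration and trial machinery.

Two generators emulate the two data regimes the simulator is built around:

* a granular porcine cohort — each animal runs the staged T/HS protocol and
  is sampled on the experimental schedule for the nine fit analytes (TNF,
  IL-6, monocytes, neutrophils, platelets, RBC, BP, and averaged pro-/anti-
  coagulation factors);
* a sparse human cohort — records with one admission O2Sat, one admission
  platelet count, zero to four MAP points, an infusion log, ISS in [5, 70],
  and a death label/time produced by the generating simulation's own death
  event.

Every subject's true local parameters are stored alongside the observations
so parameter-recovery and verification experiments have an exact reference.
Measurement noise is multiplicative log-normal for concentrations/counts
(positivity) and additive Gaussian (5 mmHg) for blood pressure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .model_core import SolverOptions, Trajectory, integrate_scenario
from .parameters import ParameterSet
from .scenarios import Scenario, build_human_scenario, build_porcine_scenario

#: the nine porcine fit analytes
PORCINE_ANALYTES = (
    "TNF", "IL6", "Mo", "Nu", "platelets", "RBC", "BP", "pro_coag_avg", "anti_coag_avg"
)
#: porcine sampling grid (min): baseline, post-hemorrhage, post-dilution,
#: post-liver-injury, then every 30 min through the monitoring window
PORCINE_SAMPLE_TIMES = (0.0, 25.0, 85.0, 95.0, 120.0, 150.0, 180.0, 210.0, 240.0, 270.0, 300.0, 330.0)
BP_NOISE_SD_MMHG = 5.0


@dataclass
class SyntheticSubject:
    id: str
    scenario: Scenario
    true_locals: Dict[str, float]
    observations: pd.DataFrame
    trajectory: Trajectory
    record: Optional[Dict] = None  # sparse human record, when applicable


@dataclass
class SyntheticCohort:
    """A generated cohort with stored ground truth."""

    subjects: List[SyntheticSubject]
    seed: int
    noise: float
    params: ParameterSet

    def observation_table(self) -> pd.DataFrame:
        frames = []
        for s in self.subjects:
            df = s.observations.copy()
            df.insert(0, "subject", s.id)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)

    def records(self) -> List[Dict]:
        return [s.record for s in self.subjects if s.record is not None]


def _sample_locals(
    ranges: Mapping[str, Tuple[float, float]], rng: np.random.Generator
) -> Dict[str, float]:
    return {k: float(rng.uniform(lo, hi)) for k, (lo, hi) in sorted(ranges.items())}


def _noisy(values: np.ndarray, analyte: str, noise: float, rng: np.random.Generator) -> np.ndarray:
    if noise <= 0:
        return values
    if analyte == "BP":
        out = values + rng.normal(0.0, BP_NOISE_SD_MMHG * noise / 0.05, len(values))
        return np.maximum(out, 5.0)
    sigma = np.sqrt(np.log1p(noise**2))  # log-normal with relative sd ≈ noise
    out = values * rng.lognormal(-0.5 * sigma**2, sigma, len(values))
    if analyte == "O2Sat":  # a saturation reading cannot exceed 100%
        out = np.minimum(out, 100.0)
    return out


def gen_porcine_cohort(
    n: int,
    seed: int = 0,
    noise: float = 0.05,
    params: Optional[ParameterSet] = None,
    solver: Optional[SolverOptions] = None,
) -> SyntheticCohort:
    """Generate ``n`` synthetic animals on the porcine T/HS protocol.

    Each animal draws its local parameters uniformly from the reference
    ranges, is randomized to a resuscitation arm (plasma-only or
    plasma+RBC, as in the fit arms), and is observed for exactly the nine
    fit analytes on the protocol sampling grid.  The 10-minute line-placement
    buffer (ISS 1) lets cytokines rise from the zero steady state to
    non-zero values by the first sample.  At ``noise=0`` observations equal
    the re-simulated model outputs exactly.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    base = params or ParameterSet.default()
    rng = np.random.default_rng(seed)
    subjects: List[SyntheticSubject] = []
    for i in range(n):
        locals_i = _sample_locals(base.local_ranges, rng)
        arm = ("plasma_only", "plasma_rbc")[int(rng.integers(2))]
        ebv = float(rng.uniform(1800.0, 2200.0))
        scen = build_porcine_scenario(arm, ebv)
        traj = integrate_scenario(scen, base.with_updates(locals_i), solver)
        rows = []
        times = np.asarray(PORCINE_SAMPLE_TIMES)
        for analyte in PORCINE_ANALYTES:
            clean = traj.value(analyte, times)
            vals = _noisy(clean, analyte, noise, rng)
            for t, v in zip(times, vals):
                rows.append({"analyte": analyte, "time_min": t, "value": float(v), "weight": 1.0})
        obs = pd.DataFrame(rows)
        subjects.append(
            SyntheticSubject(
                id=f"pig{i:02d}", scenario=scen, true_locals=locals_i,
                observations=obs, trajectory=traj,
            )
        )
    return SyntheticCohort(subjects=subjects, seed=seed, noise=noise, params=base)


# ---------------------------------------------------------------------------
# Human cohort
# ---------------------------------------------------------------------------

def _human_candidate(rng: np.random.Generator, severe: bool) -> Dict:
    """Draw one sparse human record (injury, transport, infusion log)."""
    iss = int(rng.integers(35, 66)) if severe else int(rng.integers(10, 41))
    transport = float(rng.uniform(25.0, 60.0))
    resus_start = float(rng.uniform(10.0, 40.0))
    infusions = [
        {
            "product": "crystalloid",
            "start": resus_start,
            "volume": float(rng.uniform(500.0, 2000.0)),
            "duration": float(rng.uniform(20.0, 40.0)),
        }
    ]
    if rng.random() < 0.8:  # most records include at least one plasma unit
        infusions.append(
            {
                "product": "plasma",
                "start": resus_start + float(rng.uniform(15.0, 60.0)),
                "volume": float(rng.uniform(250.0, 750.0)),
                "duration": float(rng.uniform(10.0, 30.0)),
            }
        )
    if rng.random() < 0.5:
        infusions.append(
            {
                "product": "RBC",
                "start": resus_start + float(rng.uniform(10.0, 50.0)),
                "volume": float(rng.uniform(250.0, 600.0)),
                "duration": float(rng.uniform(10.0, 30.0)),
            }
        )
    return {
        "iss": iss,
        "injury_to_admission_min": transport,
        "ventilated": bool(rng.random() < (0.6 if severe else 0.3)),
        "infusions": infusions,
        "blood_volume_initial": float(rng.uniform(4200.0, 5800.0)),
    }


def gen_human_cohort(
    n: int,
    seed: int = 0,
    mortality_fraction: float = 0.4,
    noise: float = 0.05,
    params: Optional[ParameterSet] = None,
    solver: Optional[SolverOptions] = None,
    max_attempts_factor: int = 40,
) -> SyntheticCohort:
    """Generate ``n`` sparse human trauma records with a requested death
    fraction.

    Candidates are drawn (severity-stratified), simulated, and accepted
    against survivor/non-survivor quotas until the cohort matches
    ``round(n * mortality_fraction)`` deaths; labels and death times come
    from the generating simulation's own death event, never assigned.  Every
    record carries one admission O2Sat, one admission platelet count, zero
    to four MAP points at random observation times, and its infusion log.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if not (0.0 < mortality_fraction < 1.0):
        raise ValueError("mortality_fraction must be in (0, 1)")
    base = params or ParameterSet.default()
    rng = np.random.default_rng(seed)
    want_dead = int(round(n * mortality_fraction))
    want_alive = n - want_dead
    got_dead = got_alive = 0
    subjects: List[SyntheticSubject] = []
    attempts = 0
    while got_dead < want_dead or got_alive < want_alive:
        attempts += 1
        if attempts > max_attempts_factor * n:
            raise RuntimeError("could not fill mortality quotas; check generator settings")
        severe = got_dead < want_dead
        cand = _human_candidate(rng, severe)
        locals_i = _sample_locals(base.local_ranges, rng)
        if severe:  # severe stratum: slower trauma resolution, larger wounds
            lo, hi = base.local_ranges["hemo.k_bleed"]
            locals_i["hemo.k_bleed"] = float(rng.uniform(0.5 * (lo + hi), hi))
            lo, hi = base.local_ranges["core.k_trauma_decay"]
            locals_i["core.k_trauma_decay"] = float(rng.uniform(lo, 0.5 * (lo + hi)))
        try:
            scen = build_human_scenario(cand)
            traj = integrate_scenario(scen, base.with_updates(locals_i), solver)
        except RuntimeError:
            continue
        died = traj.time_of_death is not None
        if died and got_dead >= want_dead:
            continue
        if not died and got_alive >= want_alive:
            continue
        idx = got_dead + got_alive
        sid = f"pt{idx:03d}"
        lta = traj.last_time_alive()
        n_bp = int(rng.integers(0, 5))
        bp_times = np.sort(rng.uniform(0.0, max(lta, 1.0), n_bp))
        rows = [
            {"analyte": "O2Sat", "time_min": 0.0,
             "value": float(_noisy(traj.value("O2Sat", [0.0]), "O2Sat", noise, rng)[0]),
             "weight": 1.0},
            {"analyte": "platelets", "time_min": 0.0,
             "value": float(_noisy(traj.value("platelets", [0.0]), "platelets", noise, rng)[0]),
             "weight": 1.0},
        ]
        for t, v in zip(bp_times, _noisy(traj.value("BP", bp_times), "BP", noise, rng)):
            rows.append({"analyte": "BP", "time_min": float(t), "value": float(v), "weight": 1.0})
        rows.append(
            {
                "analyte": "time_of_death" if died else "survival_to",
                "time_min": float(lta),
                "value": float(lta),
                "weight": 1.0,
            }
        )
        record = dict(cand)
        record.update(
            id=sid,
            death_flag=int(died),
            lta_min=float(lta),
            o2sat_admit=rows[0]["value"],
            platelets_admit=rows[1]["value"],
            bp_times=[float(t) for t in bp_times],
            bp_values=[r["value"] for r in rows if r["analyte"] == "BP"],
        )
        subjects.append(
            SyntheticSubject(
                id=sid, scenario=scen, true_locals=locals_i,
                observations=pd.DataFrame(rows), trajectory=traj, record=record,
            )
        )
        got_dead += int(died)
        got_alive += int(not died)
    return SyntheticCohort(subjects=subjects, seed=seed, noise=noise, params=base)


def degrade(
    observations: pd.DataFrame,
    missingness: Mapping[str, float],
    seed: int = 0,
) -> pd.DataFrame:
    """Drop observation rows independently with per-analyte probability.

    Probabilities outside [0, 1] are rejected; analytes absent from the spec
    are kept untouched.
    """
    for analyte, prob in missingness.items():
        if not (0.0 <= prob <= 1.0):
            raise ValueError(f"drop probability for {analyte} outside [0, 1]: {prob}")
    rng = np.random.default_rng(seed)
    keep = np.ones(len(observations), bool)
    analytes = observations["analyte"].to_numpy()
    u = rng.random(len(observations))
    for analyte, prob in missingness.items():
        mask = analytes == analyte
        keep[mask] &= u[mask] >= prob
    return observations.loc[keep].reset_index(drop=True)


# -- delimited-text round trips ---------------------------------------------

def write_human_records(cohort: SyntheticCohort, records_path, infusions_path) -> None:
    """Export sparse human records as the two delimited tables consumed by
    the scenario builder (records + per-record infusion log)."""
    rec_rows, inf_rows = [], []
    for s in cohort.subjects:
        r = s.record
        rec_rows.append(
            {
                "id": r["id"],
                "iss": r["iss"],
                "injury_to_admission_min": r["injury_to_admission_min"],
                "ventilated": int(r["ventilated"]),
                "lta_min": r["lta_min"],
                "death_flag": r["death_flag"],
                "o2sat_admit": r["o2sat_admit"],
                "platelets_admit": r["platelets_admit"],
                "bp_times": ";".join(f"{t:.4g}" for t in r["bp_times"]),
                "bp_values": ";".join(f"{v:.6g}" for v in r["bp_values"]),
                "blood_volume_initial": r["blood_volume_initial"],
            }
        )
        for o in r["infusions"]:
            inf_rows.append({"id": r["id"], **o})
    pd.DataFrame(rec_rows).to_csv(records_path, index=False)
    pd.DataFrame(inf_rows).to_csv(infusions_path, index=False)


def read_human_records(records_path, infusions_path) -> List[Dict]:
    recs = pd.read_csv(records_path)
    infs = pd.read_csv(infusions_path)
    out = []
    for _, row in recs.iterrows():
        log = infs[infs["id"] == row["id"]]
        rec = row.to_dict()
        rec["ventilated"] = bool(rec.get("ventilated", 0))
        rec["infusions"] = [
            {k: v for k, v in o.items() if k != "id" and pd.notna(v)}
            for o in log.to_dict("records")
        ]
        out.append(rec)
    return out
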