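"""Scenario data model, therapeutic inputs, and protocol builders.

A :class:`Scenario` is a declarative description of one simulated subject:
staged injuries (ISS-scaled), controlled-hemorrhage phases, infusion and
vasopressor schedules, ventilation, and the simulation window.  Builders are
provided for the porcine trauma/hemorrhagic-shock protocol (femur fracture,
controlled 60%-volume hemorrhage, shock, crystalloid dilution, liver injury,
randomized resuscitation arm) and for sparse human trauma records, plus the
five in-silico infusion-timing experiment transformers.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field, asdict
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd
import yaml

PRODUCTS = ("crystalloid", "colloid", "RBC", "platelets", "plasma")
#: Fraction of nominal coagulation-factor content surviving plasma processing
#: (freeze/thaw for FFP, lyophilization for FDP; the two are interchangeable).
PLASMA_FACTOR_FRACTION = 0.85


@dataclass(frozen=True)
class InjuryEvent:
    """A staged injury adding ``iss`` to the trauma state at ``time``."""

    time: float  # min, relative to t = 0
    iss: float

    def __post_init__(self) -> None:
        if not (0 <= self.iss <= 75):
            raise ValueError(f"ISS must be in [0, 75], got {self.iss}")


@dataclass
class InfusionOrder:
    """A single infusion of a fluid or blood product.

    Exactly one of ``rate``/``duration`` may be omitted; the other is derived
    from ``volume``.  Plasma (FFP or FDP — identical in the model) delivers
    coagulation factors at ``plasma_factor_fraction`` of nominal content.
    """

    product: str
    start: float  # min
    volume: float  # mL
    rate: Optional[float] = None  # mL/min
    duration: Optional[float] = None  # min
    plasma_factor_fraction: float = PLASMA_FACTOR_FRACTION

    def __post_init__(self) -> None:
        if self.product not in PRODUCTS:
            raise ValueError(f"unknown product {self.product!r}; must be one of {PRODUCTS}")
        if self.volume <= 0:
            raise ValueError("infusion volume must be > 0")
        if not (0 < self.plasma_factor_fraction <= 1):
            raise ValueError("plasma_factor_fraction must be in (0, 1]")
        if self.rate is None and self.duration is None:
            raise ValueError("one of rate or duration is required")
        if self.rate is None:
            self.rate = self.volume / self.duration
        elif self.duration is None:
            self.duration = self.volume / self.rate
        elif abs(self.rate * self.duration - self.volume) > 1e-6 * self.volume:
            raise ValueError("rate * duration must equal volume")

    @property
    def end(self) -> float:
        return self.start + self.duration


@dataclass(frozen=True)
class VasopressorOrder:
    """Vasopressor dosing window; effect is additive on BP with first-order
    washout (the model represents vasopressors phenomenologically)."""

    start: float
    duration: float
    dose_rate: float = 10.0  # effect units/min

    def __post_init__(self) -> None:
        if self.duration <= 0 or self.dose_rate < 0:
            raise ValueError("invalid vasopressor order")

    @property
    def end(self) -> float:
        return self.start + self.duration


@dataclass(frozen=True)
class BleedPhase:
    """A controlled-hemorrhage window.  The bleed-rate scale is solved at
    run time so total cumulative blood loss at ``end`` hits ``target_volume``
    (matching how loss-volume targets are recorded in the protocol)."""

    start: float
    end: float
    target_volume: float  # mL

    def __post_init__(self) -> None:
        if self.end <= self.start or self.target_volume <= 0:
            raise ValueError("invalid bleed phase")


@dataclass
class Scenario:
    """Complete declarative description of one simulated subject."""

    t_initial: float
    horizon: float
    injuries: List[InjuryEvent] = field(default_factory=list)
    infusions: List[InfusionOrder] = field(default_factory=list)
    bleed_phases: List[BleedPhase] = field(default_factory=list)
    vasopressors: List[VasopressorOrder] = field(default_factory=list)
    ventilated: bool = False
    blood_volume_initial: Optional[float] = None  # mL; overrides the parameter file
    bp_baseline: Optional[float] = None  # mmHg
    covariates: Dict = field(default_factory=dict)
    species: str = "porcine"

    def __post_init__(self) -> None:
        if self.horizon <= self.t_initial:
            raise ValueError("horizon must exceed t_initial")
        if self.species == "human":
            if not (self.t_initial < 0 <= self.horizon):
                raise ValueError("human scenarios need t_initial < 0 <= horizon")
            if self.horizon > 360:
                raise ValueError("human horizon is capped at 360 min")
        self.injuries = sorted(self.injuries, key=lambda e: e.time)

    # -- serialization --------------------------------------------------
    def to_dict(self) -> Dict:
        return {
            "subject": {
                "species": self.species,
                "t_initial": self.t_initial,
                "horizon": self.horizon,
                "ventilated": self.ventilated,
                "blood_volume_initial": self.blood_volume_initial,
                "bp_baseline": self.bp_baseline,
                "covariates": self.covariates,
            },
            "events": [asdict(e) for e in self.injuries],
            "infusions": [asdict(o) for o in self.infusions],
            "bleed_phases": [asdict(b) for b in self.bleed_phases],
            "vasopressors": [asdict(v) for v in self.vasopressors],
        }

    @classmethod
    def from_dict(cls, doc: Mapping) -> "Scenario":
        subj = doc.get("subject", {})
        return cls(
            t_initial=float(subj["t_initial"]),
            horizon=float(subj["horizon"]),
            injuries=[InjuryEvent(**e) for e in doc.get("events", [])],
            infusions=[InfusionOrder(**o) for o in doc.get("infusions", [])],
            bleed_phases=[BleedPhase(**b) for b in doc.get("bleed_phases", [])],
            vasopressors=[VasopressorOrder(**v) for v in doc.get("vasopressors", [])],
            ventilated=bool(subj.get("ventilated", False)),
            blood_volume_initial=subj.get("blood_volume_initial"),
            bp_baseline=subj.get("bp_baseline"),
            covariates=dict(subj.get("covariates", {})),
            species=subj.get("species", "porcine"),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "Scenario":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# Porcine protocol builder
# ---------------------------------------------------------------------------
# Timeline defaults (min, t = 0 at femur fracture).  Phase timings between
# fracture, cooling, and hemorrhage onset are protocol details not fully
# pinned down; the values below are the builder's documented defaults.
PORCINE_LINE_PLACEMENT_OFFSET = 10.0  # line placement 10 min before fracture
PORCINE_BLEED_START = 5.0
PORCINE_BLEED_END = 20.0  # controlled hemorrhage over 15 min
PORCINE_SHOCK_MIN = 30.0  # shock period after the controlled bleed
PORCINE_DILUTION_DURATION = 30.0
PORCINE_LIVER_INJURY = 90.0
PORCINE_RESUS_DELAY = 5.0  # resuscitation starts 5 min after liver injury
PORCINE_MONITORING = 240.0  # four hours of monitoring after liver injury
PORCINE_RESUS_RATE = 50.0  # mL/min
ISS_LINE_PLACEMENT = 1.0
ISS_FEMUR_FRACTURE = 15.0
ISS_LIVER_INJURY = 9.0
CONTROLLED_BLEED_FRACTION = 0.60  # of estimated blood volume
DILUTION_MULTIPLE = 3.0  # crystalloid volume = 3 x controlled bleed

ARMS = ("fluids", "plasma_only", "plasma_rbc")
PRE_PROTOCOLS = ("fluids", "one_unit_plasma", "equal_volume_plasma")
ONE_UNIT_PLASMA_ML = 300.0
EQUAL_VOLUME_PLASMA_ML = 1250.0


def build_porcine_scenario(
    arm: str,
    estimated_blood_volume: float,
    overrides: Optional[Mapping] = None,
) -> Scenario:
    """Build the porcine T/HS protocol scenario for one animal.

    Timeline: line placement (ISS 1) 10 min before the femur fracture
    (ISS 15, t = 0); controlled hemorrhage of 60% of the estimated blood
    volume; 30 min of shock; crystalloid dilution at three times the
    controlled-bleed volume; Grade V liver injury (ISS 9); then the
    randomized resuscitation arm at 50 mL/min with total volume equal to the
    controlled bleed.  The plasma+RBC arm is dosed as four quarter-volume
    boluses ordered RBC, plasma, RBC, plasma.  Monitoring continues for four
    hours after the liver injury.

    ``overrides`` may supply ``resus_volume`` (mL, replaces the default
    controlled-bleed volume), ``dilution_volume`` (mL),
    ``pre_protocol`` (one of fluids / one_unit_plasma / equal_volume_plasma),
    and ``bp_baseline``.
    """
    if arm not in ARMS:
        raise ValueError(f"unknown arm {arm!r}; must be one of {ARMS}")
    if estimated_blood_volume <= 0:
        raise ValueError("estimated_blood_volume must be > 0")
    ov = dict(overrides or {})
    pre_protocol = ov.get("pre_protocol", "fluids")
    if pre_protocol not in PRE_PROTOCOLS:
        raise ValueError(f"unknown pre_protocol {pre_protocol!r}")

    v_controlled = CONTROLLED_BLEED_FRACTION * estimated_blood_volume
    resus_volume = float(ov.get("resus_volume", v_controlled))
    dilution_volume = float(ov.get("dilution_volume", DILUTION_MULTIPLE * v_controlled))

    injuries = [
        InjuryEvent(time=-PORCINE_LINE_PLACEMENT_OFFSET, iss=ISS_LINE_PLACEMENT),
        InjuryEvent(time=0.0, iss=ISS_FEMUR_FRACTURE),
        InjuryEvent(time=PORCINE_LIVER_INJURY, iss=ISS_LIVER_INJURY),
    ]
    bleed_phases = [
        BleedPhase(start=PORCINE_BLEED_START, end=PORCINE_BLEED_END, target_volume=v_controlled)
    ]

    dilution_start = PORCINE_BLEED_END + PORCINE_SHOCK_MIN
    infusions: List[InfusionOrder] = []
    if pre_protocol == "fluids":
        infusions.append(
            InfusionOrder(
                "crystalloid",
                start=dilution_start,
                volume=dilution_volume,
                duration=PORCINE_DILUTION_DURATION,
            )
        )
    elif pre_protocol == "one_unit_plasma":
        infusions.append(
            InfusionOrder(
                "plasma",
                start=dilution_start,
                volume=ONE_UNIT_PLASMA_ML,
                rate=PORCINE_RESUS_RATE,
            )
        )
    else:  # equal_volume_plasma
        infusions.append(
            InfusionOrder(
                "plasma",
                start=dilution_start,
                volume=EQUAL_VOLUME_PLASMA_ML,
                duration=PORCINE_DILUTION_DURATION,
            )
        )

    resus_start = PORCINE_LIVER_INJURY + PORCINE_RESUS_DELAY
    if arm == "fluids":
        infusions.append(
            InfusionOrder(
                "crystalloid", start=resus_start, volume=resus_volume, rate=PORCINE_RESUS_RATE
            )
        )
    elif arm == "plasma_only":
        infusions.append(
            InfusionOrder(
                "plasma", start=resus_start, volume=resus_volume, rate=PORCINE_RESUS_RATE
            )
        )
    else:  # plasma_rbc: 1:1 dosing as four quarter-volume boluses
        quarter = resus_volume / 4.0
        t = resus_start
        for product in ("RBC", "plasma", "RBC", "plasma"):
            infusions.append(
                InfusionOrder(product, start=t, volume=quarter, rate=PORCINE_RESUS_RATE)
            )
            t += quarter / PORCINE_RESUS_RATE

    return Scenario(
        t_initial=-PORCINE_LINE_PLACEMENT_OFFSET,
        horizon=PORCINE_LIVER_INJURY + PORCINE_MONITORING,
        injuries=injuries,
        infusions=infusions,
        bleed_phases=bleed_phases,
        blood_volume_initial=estimated_blood_volume,
        bp_baseline=ov.get("bp_baseline"),
        covariates={"arm": arm, "pre_protocol": pre_protocol},
        species="porcine",
    )


# ---------------------------------------------------------------------------
# Human record builder
# ---------------------------------------------------------------------------

def build_human_scenario(record: Mapping) -> Scenario:
    """Build a human scenario from a sparse trauma record.

    ``record`` must provide ``iss``, ``injury_to_admission_min``, an
    ``infusions`` list (dicts with product/start/volume and rate or
    duration), and may provide ``ventilated``, ``blood_volume_initial``,
    ``bp_baseline``, ``horizon``, and an ``id``.  Time zero is hospital
    admission; the injury occurs at ``t_initial = -injury_to_admission_min``;
    simulation proceeds to at most 360 min.  Records with an empty infusion
    log are rejected (presumed-missing data).
    """
    infusion_rows = record.get("infusions") or []
    if len(infusion_rows) == 0:
        raise ValueError("record has zero infusions; excluded as presumed-missing data")
    transport = float(record["injury_to_admission_min"])
    if transport <= 0:
        raise ValueError("injury_to_admission_min must be > 0")
    horizon = min(360.0, float(record.get("horizon", 360.0)))
    infusions = [
        row if isinstance(row, InfusionOrder) else InfusionOrder(**row) for row in infusion_rows
    ]
    return Scenario(
        t_initial=-transport,
        horizon=horizon,
        injuries=[InjuryEvent(time=-transport, iss=float(record["iss"]))],
        infusions=infusions,
        ventilated=bool(record.get("ventilated", False)),
        blood_volume_initial=record.get("blood_volume_initial"),
        bp_baseline=record.get("bp_baseline"),
        covariates={"id": record.get("id"), "iss": float(record["iss"])},
        species="human",
    )


def iss_filter(records: Iterable[Mapping]) -> List[Mapping]:
    """Retain records with 5 <= ISS <= 70; drop outliers and missing ISS."""
    kept = []
    for rec in records:
        iss = rec.get("iss")
        if iss is None or (isinstance(iss, float) and iss != iss):
            warnings.warn(f"record {rec.get('id')} rejected: missing ISS")
            continue
        if 5 <= float(iss) <= 70:
            kept.append(rec)
    return kept


# ---------------------------------------------------------------------------
# In-silico experiment transformers
# ---------------------------------------------------------------------------
EXPERIMENT_SHIFTS = {"exp2": -30.0, "exp3": -10.0, "exp4": 10.0, "exp5": 30.0}


def apply_experiment(
    scenario: Scenario, experiment: str, cohort_stats: Optional[Mapping] = None
) -> Scenario:
    """Transform a baseline human scenario into one of the five in-silico
    infusion-timing experiments.

    exp1 adds one plasma infusion 15 min post-injury (pre-hospital), with
    volume and duration equal to the cohort's average real first plasma
    infusion (``cohort_stats['mean_plasma_volume'/'mean_plasma_duration']``).
    exp2..exp5 shift every infusion start by -30/-10/+10/+30 min.  Shifts
    that would start an infusion before the injury are clamped to the injury
    time with a warning.
    """
    out = copy.deepcopy(scenario)
    injury_time = min(e.time for e in out.injuries) if out.injuries else out.t_initial
    if experiment == "exp1":
        if cohort_stats is None:
            raise ValueError("exp1 requires cohort_stats with the average first plasma infusion")
        vol = float(cohort_stats["mean_plasma_volume"])
        dur = float(cohort_stats["mean_plasma_duration"])
        out.infusions.append(
            InfusionOrder("plasma", start=injury_time + 15.0, volume=vol, duration=dur)
        )
    elif experiment in EXPERIMENT_SHIFTS:
        shift = EXPERIMENT_SHIFTS[experiment]
        shifted = []
        for order in out.infusions:
            new_start = order.start + shift
            if new_start < injury_time:
                warnings.warn(
                    f"{experiment}: infusion at t={order.start} clamped to injury time"
                )
                new_start = injury_time
            shifted.append(
                InfusionOrder(
                    order.product,
                    start=new_start,
                    volume=order.volume,
                    rate=order.rate,
                    plasma_factor_fraction=order.plasma_factor_fraction,
                )
            )
        out.infusions = shifted
    elif experiment in ("exp0", "baseline"):
        pass  # identity transform
    else:
        raise ValueError(f"unknown experiment {experiment!r}")
    out.infusions.sort(key=lambda o: o.start)
    return out


# ---------------------------------------------------------------------------
# Infusion input fluxes
# ---------------------------------------------------------------------------

@dataclass
class InfusionFluxes:
    """Instantaneous inputs delivered by the active infusion orders.

    ``volume_rate`` is the total volume inflow (mL/min).  Species rates are
    products of the per-order volume rate and the product's species
    concentration; dilution of everything else follows from the volume
    inflow during integration.
    """

    volume_rate: float = 0.0
    procoag_rate: float = 0.0  # relative activity * mL/min
    anticoag_rate: float = 0.0
    rbc_rate: float = 0.0  # relative mass * mL/min
    platelet_rate: float = 0.0  # 10^3/uL * mL/min


def infusion_effects(orders: Sequence[InfusionOrder], t: float, p) -> InfusionFluxes:
    """Sum the input fluxes of every order active at time ``t``.

    All products add volume at the order rate.  Plasma delivers pro- and
    anti-coagulation factors at ``plasma_factor_fraction`` (default 0.85) of
    nominal plasma content; RBC orders add red-cell mass; platelet orders add
    platelets; crystalloid and colloid deliver volume only (and therefore
    dilute).  Overlapping orders sum.
    """
    fx = InfusionFluxes()
    for order in orders:
        if not (order.start <= t < order.end):
            continue
        fx.volume_rate += order.rate
        if order.product == "plasma":
            conc = order.plasma_factor_fraction * p.plasma_factor_conc
            fx.procoag_rate += order.rate * conc
            fx.anticoag_rate += order.rate * conc
        elif order.product == "RBC":
            fx.rbc_rate += order.rate * p.rbc_product_conc
        elif order.product == "platelets":
            fx.platelet_rate += order.rate * p.platelet_product_conc
    return fx
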