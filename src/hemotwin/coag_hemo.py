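"""Coagulation cascade, hemodynamics, bleeding, and oxygen transfer.

The coagulation module lumps the clotting cascade into generalized pro- and
anti-coagulation species (inactive/active each, healthy totals normalized to
1), platelets, red-cell mass, and a clot pool.  Trauma and IL-6 drive
inactive→active pro-coagulation conversion; active pro-coagulation combines
with platelets to form clot; trauma accelerates clot degradation
(fibrinolysis).  Hemodynamics track a dynamic blood volume; mean arterial
pressure is an algebraic function of volume, circulating NO and vasopressor
effect, and bleeding is pressure-driven and clot-inhibited.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Tuple

#: Canonical factor panel names (percent of normal activity).
PRO_FACTORS = ("FII", "FV", "FVII", "FVIII", "FIX", "FX", "FXI", "FXII")
ANTI_FACTORS = ("ATIII", "PC")


@dataclass
class CoagState:
    """Coagulation pools. Pro/anti-coagulation activities are relative to a
    healthy total of 1.0 (inactive + active); clot units are arbitrary with
    healthy clot ~ 0."""

    platelets: float = 300.0  # 10^3/uL
    rbc: float = 1.0  # relative mass
    procoag_inactive: float = 1.0
    procoag_active: float = 0.0
    anticoag_inactive: float = 1.0
    anticoag_active: float = 0.0
    clot: float = 0.0

    def validate(self) -> None:
        for name, v in self.__dict__.items():
            if v < 0:
                raise ValueError(f"CoagState.{name} must be >= 0, got {v}")


@dataclass
class HemoState:
    """Hemodynamic observables at one instant."""

    blood_volume: float  # mL
    bp: float  # mmHg, mean arterial
    o2sat: float  # %
    bled_volume: float = 0.0  # cumulative mL


def _fm(v: float, x: float, hill: float = 2.0) -> float:
    if v <= 0.0:
        return 0.0
    vh = v**hill
    return vh / (vh + x**hill)


# ---------------------------------------------------------------------------
# Coagulation kinetics (shared by the standalone RHS and the full model)
# ---------------------------------------------------------------------------

def procoag_activation_flux(
    procoag_inactive: float,
    procoag_active: float,
    anticoag_active: float,
    il6: float,
    trauma: float,
    p,
) -> float:
    """Inactive→active pro-coagulation conversion rate.

    Driven by trauma and IL-6, self-amplifying through active pro-coagulation,
    and inhibited by active anti-coagulation.
    """
    drive = (
        p.k_coag_trauma * trauma / 75.0
        + p.k_coag_il6 * _fm(il6, p.x_coag_il6)
        + p.k_coag_self * _fm(procoag_active, p.x_coag_self)
    )
    inhibition = 1.0 / (1.0 + anticoag_active / p.x_anticoag)
    return drive * inhibition * procoag_inactive


def clot_formation_rate(procoag_active: float, platelets: float, p) -> float:
    """Clot formation: active pro-coagulation combining with platelets."""
    return p.k_clot * procoag_active * platelets


def clot_degradation_rate(clot: float, trauma: float, p) -> float:
    """First-order clot lysis, accelerated by trauma (fibrinolysis)."""
    return p.d_clot * (1.0 + p.k_fib_trauma * trauma / 75.0) * clot


def coagulation_rhs(state: CoagState, p, il6: float, trauma: float) -> CoagState:
    """Time derivatives of the coagulation pools (no infusion/dilution terms).

    At the healthy baseline (trauma=0, il6=0, pools at their normalized
    resting values) every derivative is zero by construction: inactive pools
    carry a turnover source balancing their decay.
    """
    state.validate()
    act = procoag_activation_flux(
        state.procoag_inactive, state.procoag_active, state.anticoag_active, il6, trauma, p
    )
    form = clot_formation_rate(state.procoag_active, state.platelets, p)
    anti_act = p.k_anti_act * state.procoag_active * state.anticoag_inactive
    return CoagState(
        platelets=p.d_platelets * (p.platelets_baseline - state.platelets)
        - p.c_plt_consumption * form,
        rbc=p.d_rbc * (1.0 - state.rbc),
        procoag_inactive=p.d_procoag_inactive * (1.0 - state.procoag_inactive) - act,
        procoag_active=act
        - p.d_procoag_active * state.procoag_active
        - p.c_procoag_consumption * form,
        anticoag_inactive=p.d_anticoag_inactive * (1.0 - state.anticoag_inactive) - anti_act,
        anticoag_active=anti_act - p.d_anticoag_active * state.anticoag_active,
        clot=form - clot_degradation_rate(state.clot, trauma, p),
    )


# ---------------------------------------------------------------------------
# Hemodynamics
# ---------------------------------------------------------------------------

def blood_pressure(
    blood_volume: float, no: float, vasopressor_dose: float, p
) -> float:
    """Mean arterial pressure from blood volume, NO level, and vasopressors.

    At baseline volume, baseline NO and no vasopressor this returns the
    subject's baseline MAP exactly.  Below baseline volume, pressure falls as
    a power of the volume fraction; above baseline the response saturates
    (vascular capacitance) while remaining strictly increasing.  NO above its
    baseline lowers pressure, below baseline raises it.
    """
    if blood_volume < 0 or no < 0 or vasopressor_dose < 0:
        raise ValueError("blood_pressure inputs must be >= 0")
    r = blood_volume / p.blood_volume_initial
    if r <= 1.0:
        g = r**p.k_bp_vol
    else:
        # C1-continuous saturating branch: slope k_bp_vol at r=1
        g = 1.0 + p.k_bp_vol * p.k_bp_sat * (1.0 - math.exp(-(r - 1.0) / p.k_bp_sat))
    k = p.K_bloodpressure_no
    f_no = (1.0 + k) / (1.0 + k * no / p.no_baseline)
    return p.bp_baseline * g * f_no + p.k_vaso * vasopressor_dose


def bleeding_rate(
    bp: float, clot: float, trauma: float, blood_volume: float, p, controlled_scale: float = 0.0
) -> float:
    """Hemorrhage rate in mL/min.

    Trauma opens the wound; higher pressure drives faster loss; clot slows
    it; the rate vanishes smoothly as the circulation empties.  A controlled
    hemorrhage phase (catheter withdrawal) adds a scripted component that
    shares the pressure/clot dependence, scaled by ``controlled_scale``.
    """
    if min(bp, clot, trauma, blood_volume) < 0:
        raise ValueError("bleeding_rate inputs must be >= 0")
    shape = (bp / p.bp_baseline) / (1.0 + clot / p.x_bleed_clot)
    soft_empty = 1.0 - math.exp(-blood_volume / p.v_bleed_soft)
    wound = p.k_bleed * trauma / 75.0
    return (wound + controlled_scale) * shape * soft_empty


def oxygen_saturation(epal: float, ventilated: bool, p) -> float:
    """Arterial O2 saturation (%) from the active lung-barrier burden EPAL.

    98% with an intact barrier, monotone decreasing in EPAL; ventilation
    attenuates the EPAL effect.
    """
    if epal < 0:
        raise ValueError("EPAL must be >= 0")
    burden = p.k_o2_epal * epal / p.ecl_baseline
    if ventilated:
        burden /= 1.0 + p.vent_benefit
    return 98.0 / (1.0 + burden)


# ---------------------------------------------------------------------------
# Factor panel grouping
# ---------------------------------------------------------------------------

def group_coag_factors(panel: Mapping[str, float]) -> Tuple[float, float]:
    """Average a 10-factor panel into (pro_avg, anti_avg), percent of normal.

    Pro: FII, FV, FVII, FVIII, FIX, FX, FXI, FXII.  Anti: ATIII, PC.  Values
    are interpreted as active+inactive sums.
    """
    for name in PRO_FACTORS + ANTI_FACTORS:
        if name not in panel:
            raise KeyError(f"missing factor {name}")
    pro_avg = sum(float(panel[f]) for f in PRO_FACTORS) / len(PRO_FACTORS)
    anti_avg = sum(float(panel[f]) for f in ANTI_FACTORS) / len(ANTI_FACTORS)
    return pro_avg, anti_avg


def read_factor_panel(path) -> Mapping[str, float]:
    """Read a delimited factor panel with columns factor_name, value_pct."""
    import pandas as pd

    df = pd.read_csv(path)
    if not {"factor_name", "value_pct"} <= set(df.columns):
        raise ValueError("factor panel must have columns factor_name, value_pct")
    return dict(zip(df["factor_name"], df["value_pct"].astype(float)))
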