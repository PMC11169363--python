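"""Composite damage score and the death event.

The clinical output of the simulator is a scalar "damage" rate built from
four physiological insults: hypotension, hypoxemia, IL-6 excess, and the
injury burden itself.  Damage is accumulated over time (AUC_DAMAGE) and a
global threshold on that integral triggers death.  Damage and death are pure
observables: they never feed back into the dynamical state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

#: Physiological ceiling of arterial oxygen saturation (%).
O2SAT_MAX = 98.0
#: Maximum of the Injury Severity Score scale.
ISS_MAX = 75.0
#: Hill exponent used by every saturating damage term.
HILL = 2.0
#: Cumulative damage (damage·min) at which death is triggered.
DEATH_THRESHOLD = 276.53


def fm(v: float, x: float, hill: float = HILL) -> float:
    """Saturating Hill response ``v**h / (v**h + x**h)``.

    Monotone increasing in ``v``, 0 at ``v=0``, 0.5 at ``v=x``, and bounded
    above by 1.
    """
    if x <= 0:
        raise ValueError(f"fm half-saturation constant must be > 0, got {x}")
    if v < 0:
        raise ValueError(f"fm input must be >= 0, got {v}")
    if hill <= 0:
        raise ValueError(f"fm Hill exponent must be > 0, got {hill}")
    if v == 0.0:
        return 0.0
    vh = v**hill
    return vh / (vh + x**hill)


@dataclass(frozen=True)
class DamageParams:
    """Constants of the four damage components.

    ``k_*`` are component gains (damage units), ``x_*`` half-saturation
    scales, ``*_thresh`` the physiological thresholds below/above which a
    deficit starts to count.
    """

    k_damage_bp: float = 1.0
    x_damage_bp: float = 10.0
    bp_damage_thresh: float = 60.0  # mmHg
    k_damage_o2sat: float = 1.0
    o2sat_damage_thresh: float = 90.0  # %
    k_damage_il6: float = 1.0
    x_damage_il6: float = 250.0
    il6_damage_thresh: float = 250.0  # pg/mL
    k_damage_trauma: float = 1.0

    def __post_init__(self) -> None:
        for name in (
            "k_damage_bp",
            "x_damage_bp",
            "bp_damage_thresh",
            "k_damage_o2sat",
            "o2sat_damage_thresh",
            "k_damage_il6",
            "x_damage_il6",
            "il6_damage_thresh",
            "k_damage_trauma",
        ):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"DamageParams.{name} must be finite and >= 0, got {v}")


def bp_damage(bp: float, p: DamageParams) -> float:
    """Hypotension damage: Hill response to the blood-pressure deficit."""
    deficit = max(p.bp_damage_thresh - bp, 0.0)
    return p.k_damage_bp * fm(deficit, p.x_damage_bp, HILL)


def o2sat_damage(o2sat: float, p: DamageParams) -> float:
    """Hypoxemia damage: linear in the saturation deficit, scaled by 1/98."""
    deficit = max(p.o2sat_damage_thresh - o2sat, 0.0)
    return p.k_damage_o2sat * deficit / O2SAT_MAX


def il6_damage(il6: float, p: DamageParams) -> float:
    """Inflammatory damage: Hill response to IL-6 excess above threshold."""
    excess = max(il6 - p.il6_damage_thresh, 0.0)
    return p.k_damage_il6 * fm(excess, p.x_damage_il6, HILL)


def trauma_damage(trauma: float, p: DamageParams) -> float:
    """Injury-burden damage, linear in the ISS-scaled trauma state."""
    return p.k_damage_trauma * trauma / ISS_MAX


def total_damage(
    bp_component: float,
    o2sat_component: float,
    il6_component: float,
    trauma_component: float,
) -> float:
    """Composite damage rate: the sum of the four components."""
    for v in (bp_component, o2sat_component, il6_component, trauma_component):
        if v < 0:
            raise ValueError("damage components must be non-negative")
    return bp_component + o2sat_component + il6_component + trauma_component


def damage_rate(bp: float, o2sat: float, il6: float, trauma: float, p: DamageParams) -> float:
    """Composite damage rate evaluated from raw physiological inputs."""
    return total_damage(
        bp_damage(bp, p), o2sat_damage(o2sat, p), il6_damage(il6, p), trauma_damage(trauma, p)
    )


@dataclass
class DeathModel:
    """Accumulates the damage integral and latches the death event.

    Once ``auc_damage`` crosses ``death_threshold`` the event is triggered
    and ``time_of_death`` is set by linear interpolation to the crossing;
    later updates keep accumulating AUC but never move the death time
    (simulation continues to the horizon even after death).
    """

    death_threshold: float = DEATH_THRESHOLD
    auc_damage: float = 0.0
    triggered: bool = False
    time_of_death: Optional[float] = field(default=None)

    def step(self, damage_rate: float, dt: float, t_start: float) -> "DeathModel":
        """Advance the AUC by ``damage_rate * dt`` starting at time ``t_start``."""
        if dt <= 0:
            raise ValueError("dt must be > 0")
        if damage_rate < 0:
            raise ValueError("damage rate must be >= 0")
        auc_new = self.auc_damage + damage_rate * dt
        if not self.triggered and auc_new >= self.death_threshold:
            # linear interpolation of the crossing inside the step
            frac = (self.death_threshold - self.auc_damage) / (damage_rate * dt)
            self.time_of_death = t_start + frac * dt
            self.triggered = True
        self.auc_damage = auc_new
        return self


def step_death(
    auc_before: float, damage_rate: float, dt: float, model: DeathModel, t_start: float = 0.0
) -> DeathModel:
    """Functional wrapper over :meth:`DeathModel.step` (AUC passed explicitly)."""
    model.auc_damage = auc_before
    return model.step(damage_rate, dt, t_start=t_start)


def last_time_alive(trajectory) -> float:
    """Final alive time of a trajectory: its death time if death triggered,
    otherwise the simulation horizon."""
    if trajectory is None or not getattr(trajectory, "complete", True):
        raise ValueError("trajectory is incomplete")
    tod = trajectory.time_of_death
    return float(tod) if tod is not None else float(trajectory.horizon)
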