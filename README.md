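# hemotwin

A mechanistic digital-twin simulator of traumatic injury with hemorrhagic
shock (T/HS), for researchers studying damage-control resuscitation: which
fluids and blood products to give, how much, and — above all — when.

The core is a three-compartment (blood / lung / tissue) ordinary
differential equation model of the acute inflammatory response coupled to a
lumped coagulation cascade and dynamic hemodynamics. An injury, quantified
by the Injury Severity Score (ISS), perturbs the system from a healthy
steady state: monocytes (Mo) and neutrophils (Nu) activate in all three
compartments, epithelial-cell barriers (blood–lung, blood–tissue) activate,
activated cells migrate from blood into lung and tissue (never back),
produce pro-inflammatory cytokines (TNF-α, IL-1, IL-6) and NO/iNOS, while
IL-10 inhibits activation and iNOS production. Trauma and IL-6 activate the
coagulation cascade (inactive → active pro-coagulation), active factors
combine with platelets to form clot, and trauma accelerates clot lysis
(fibrinolysis). Bleeding is pressure-driven and clot-inhibited; blood volume
and mean arterial pressure are dynamic; activated lung-barrier cells (the
EPAL observable) impair oxygen transfer. Resuscitation inputs — crystalloid,
colloid, packed RBC, platelets, and plasma (FFP/FDP, interchangeable, with
coagulation factors reduced 15% by processing) — add volume and species and
dilute what they do not carry.

The clinical outcome is a composite damage rate

    Damage = bp_damage + O2Sat_damage + il6_damage + trauma_damage

with `bp_damage = k·fm(max(thresh − BP, 0), x, 2)`,
`O2Sat_damage = k·max(thresh − O2Sat, 0)/98`,
`il6_damage = k·fm(max(IL6 − thresh, 0), x, 2)`,
`trauma_damage = k·trauma/75`, where `fm(v,x,h) = vʰ/(vʰ + xʰ)`.
Cumulative damage is tracked as AUC_DAMAGE; when it crosses the global
threshold **276.53** the death event fires (located by ODE event
root-finding). Integration continues to the horizon; the time of death is
latched. Damage and death never feed back into the dynamics.

Around the simulator the package provides:

- **Protocol builders** — the staged porcine T/HS protocol (line placement
  ISS 1 ten minutes before a femur fracture ISS 15, controlled hemorrhage of
  60% of estimated blood volume, 30 min shock, 3× crystalloid dilution,
  liver injury ISS 9, randomized resuscitation at 50 mL/min) and sparse
  human trauma records (injury at t_initial < 0, admission at t = 0,
  horizon capped at 360 min, ISS outliers outside [5, 70] excluded).
- **Calibration** — weighted least-squares fitting by a seeded sequential
  Monte Carlo over global (shared) and local (per-subject) parameters, with
  physiologic heuristics (cytokine peaks < 10,000 pg/mL, BP within
  20–250 mmHg, NO < 1,000 µmol/L, minimum bleed of 30% of healthy blood
  volume), half-fit-half-predict verification, and a human re-tuning stage
  that opens only the NO-pathway and damage/death globals.
- **In-silico trials** — seven virtual porcine arms (100 members each)
  contrasting crystalloid vs hemostatic resuscitation, and five human
  infusion-timing experiments (pre-hospital plasma at injury + 15 min;
  shifting every infusion by −30/−10/+10/+30 min) reported as per-patient
  percent changes against each patient's own baseline schedule.
- **Synthetic cohorts** — ground-truth-known porcine and human cohorts
  (the nine porcine fit analytes on the protocol schedule; sparse human
  records with one admission O2Sat, one platelet count, 0–4 MAP points, an
  infusion log, and a simulation-derived death label), so every stage is
  testable without restricted data.

## Worked example

Simulate one porcine plasma+RBC animal and inspect the outcome:

```python
import numpy as np
from hemotwin import ParameterSet, build_porcine_scenario, integrate_scenario

params = ParameterSet.default()
scenario = build_porcine_scenario("plasma_rbc", estimated_blood_volume=2000.0)
traj = integrate_scenario(scenario, params)
f = traj.frame
print(f"bled {traj.bled_volume:.0f} mL of 2000 mL")
print(f"controlled-phase loss at t=20: {np.interp(20.0, f.time_min, f.bled):.0f} mL")
print(f"AUC damage {traj.auc_damage:.0f}; outcome: "
      f"{'died' if traj.time_of_death else 'survived the 4 h window'}")
```

prints

```
bled 1604 mL of 2000 mL
controlled-phase loss at t=20: 1200 mL
AUC damage 247; outcome: survived the 4 h window
```

— the controlled hemorrhage removes exactly 60% of the estimated blood
volume (1200 mL) by the end of its phase; afterwards the liver injury adds
dynamic, pressure-dependent bleeding for ~400 mL more, and the animal stays
below the death threshold of 276.53 damage·min.

The same machinery runs from the shell:

```sh
hemotwin synth --kind porcine --n 6 --seed 1 --out runs/data
hemotwin fit --data runs/data --config fit.yaml --seed 1 --out runs/fit
hemotwin cohort --n 100 --seed 1 --out runs/arms
hemotwin experiment --n 10 --seed 1 --out runs/exps
```

Every command writes a `manifest.json` (input hashes, seed, package
version) so runs are reproducible bit-for-bit.

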