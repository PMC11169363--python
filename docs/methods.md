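# Methods

## Model structure

The dynamical state has 44 coordinates: resting/active monocytes and
neutrophils in blood, lung, and tissue; TNF-α, IL-1, IL-6, IL-10 in each
compartment; NO and iNOS; resting/active epithelial cells on the blood–lung
barrier (the active pool is the EPAL observable) and the blood–tissue
barrier; DAMPs; the ISS-scaled trauma input; platelets, relative RBC mass,
inactive/active pro- and anti-coagulation, clot; blood volume, cumulative
bled and infused volumes, vasopressor effect; and the damage integral
AUC_DAMAGE carried as an extra ODE coordinate so the death event can be
located by root-finding rather than post-hoc summation.

Functional forms follow one family throughout: mass-action activation,
saturating promotion through the Hill-type response
`fm(v, x, 2) = v²/(v² + x²)`, and `1/(1 + inhibitor/x)` inhibition. The
activation stimulus for each cell population combines the trauma level
(normalized by the ISS maximum of 75), local pro-inflammatory cytokines
through `fm`, and — for blood-contacting populations — active
pro-coagulation factor; IL-10 divides the whole stimulus and separately
inhibits iNOS production by all cell types. Migration of active cells runs
only from blood to lung and blood to tissue, with the blood efflux equal by
construction to the sum of the compartment gains.

Every resting pool carries a turnover source balancing its first-order loss
at baseline, so the healthy steady state is exact: all active pools,
pro-inflammatory cytokines, DAMPs, trauma, and clot are zero; NO sits at a
constitutive baseline (10 µmol/L by default) maintained by a basal
production term, which is what lets below-baseline NO raise blood pressure
and above-baseline NO lower it.

### Hemodynamics

Mean arterial pressure is algebraic in volume, NO, and vasopressor effect:
below baseline volume it scales as a power of the volume fraction; above
baseline it saturates (a C¹ capacitance branch) while remaining strictly
increasing, so large crystalloid loads raise pressure without unbounded
hypertension. The NO factor is `(1+k)/(1+k·NO/NO_baseline)`, anchored so
baseline volume + baseline NO + no vasopressor returns the subject's
baseline MAP exactly. Bleeding is `k_bleed·(trauma/75)` shaped by
`(BP/BP_baseline)`, inhibited by `1/(1+clot/x)`, and extinguished smoothly
as the circulation empties (`1−exp(−V/100 mL)`; at physiologic volumes this
factor is 1 to machine precision). Blood volume changes only through
bleeding and infusion, so the mass balance `V(t) = V₀ − ∫bleed + ∫infuse`
holds to solver precision; there is no fluid-redistribution term, which
means large crystalloid loads stay intravascular and their dilutional
effect persists — a deliberate simplification that keeps the volume ledger
auditable. Oxygen saturation is `98/(1 + k·EPAL/EPAL_baseline)`, with
ventilation dividing the EPAL burden by `(1 + vent_benefit)`.

### Infusions and dilution

Each product delivers volume at its order rate; plasma additionally carries
pro- and anti-coagulation factors at 0.85 of nominal content (processing
loss; FFP and FDP are one product, "plasma"), RBC units carry red-cell mass
at twice baseline concentration, platelet units carry concentrate. Blood
species (cytokines, NO, platelets, RBC, coagulation factors) follow a
mixing law `dC = Σ rate_p·(C_in,p − C)/V`, so factor-free fluids dilute and
factor-bearing products restore. Bleeding removes whole blood and therefore
leaves concentrations unchanged. Cell pools are treated as counts, not
concentrations, and are not diluted.

### Integration

Segment-wise stiff integration (LSODA, rtol 1e−6 / atol 1e−9 by default)
with exact breakpoints at every injury, infusion start/end, bleed-phase
boundary, vasopressor window, and ventilation start; injuries add their ISS
to the trauma state as jumps between segments. The death event is an ODE
event on `AUC_DAMAGE − 276.53` (direction up, non-terminal): the crossing
time is latched and integration continues to the horizon. The AUC
accumulates from `t_initial`, so pre-admission injury time contributes for
humans. Transient solver undershoot is guarded by clamping the RHS inputs
at zero; a coordinate more negative than 1e−6 at a segment end is a hard
error naming the coordinate (1e−6 rather than a tighter bound because
adaptive-step local error can undershoot the atol scale transiently — the
RHS clamp makes such excursions self-correcting).

### Controlled hemorrhage

Catheter phases are scripted: within the phase an extra bleed component
(sharing the pressure/clot shape) is scaled so that *total cumulative blood
loss at phase end* equals the protocol target (60% of estimated blood
volume), matching how loss targets are recorded; the scale is solved by
Brent root-finding over repeated phase-local integrations. The dynamic
wound bleed keeps running concurrently, so the tuned scale absorbs it.

## Porcine protocol defaults

Published timings pin the order of events but not every interval; the
builder's documented defaults (minutes, t = 0 at the femur fracture) are:
line placement ISS 1 at −10 (this 10-min buffer lifts cytokines off zero
by the first sample); controlled bleed over [5, 20]; shock to 50;
crystalloid dilution (3× the controlled-bleed volume) over [50, 80]; liver
injury ISS 9 at 90; arm resuscitation from 95 at 50 mL/min with total
volume equal to the controlled bleed (the plasma+RBC arm as four
back-to-back quarter boluses RBC, plasma, RBC, plasma); horizon 330
(four hours of monitoring after the liver injury). Hypothermia is not
modeled (no temperature state). Vasopressors are an additive BP input with
first-order washout — a phenomenological stand-in, since only their
presence as scenario inputs is specified.

## Calibration

The objective is `Σ_subjects [Σ w·(model − obs)² + heuristic penalty]`.
Default weights are per-subject, per-analyte inverse variances (scale-free
residuals), floored at (10% of the analyte's mean level)² — plain inverse
variance is degenerate on sparse records, where a singleton analyte or two
near-identical BP points would otherwise acquire divergent weight.
Outcome records are event times, not repeated measures: they carry a fixed
5-minute residual scale, so a 5-minute miss on the death time costs one
objective unit and outcome fidelity dominates when it is badly wrong.
Death-time records enter as two-sided residuals in minutes. Survivor
records force no death event before their horizon: a model death earlier
than the observed last-time-alive pays the one-sided quadratic residual
plus a fixed label penalty (100 objective units), so the constraint stays
binding even for deaths a fraction of a minute before the horizon, where a
quadratic alone would be vanishingly small.
Heuristic penalties are quadratic hinges on relative violation
(scale 1e4): cytokine peaks above 10,000 pg/mL (with tighter 5,000 pg/mL
physiologic ceilings for IL-1 and IL-10), MAP outside 20–250 mmHg, NO above
1,000 µmol/L, and total bleed below 30% of the subject's healthy blood
volume, all assessed until death or the 6-hour cut-off.

The optimizer is a sequential Monte Carlo with adaptive Boltzmann selection
(temperature set by the interquartile score spread), systematic resampling,
a Gaussian perturbation kernel shrinking geometrically from 0.3 of each
prior width, reflection at the prior bounds, and elitist re-injection of
the incumbent. Because the objective decomposes per subject and each
subject's locals touch only its own score, local blocks are reselected
per subject while globals are selected on the total — this blocked scheme
is what makes recovery work at small particle counts. Effective sample
size is tracked per generation and resampling events below N/2 are logged.
The reported best objective is a running minimum, hence non-increasing by
construction, and identical seed + configuration reproduce the result
bit-for-bit.

The reference parameter file marks exactly 33 keys fit-eligible: 29
global-fit (activation, migration, cytokine production, the four NO
parameters, coagulation couplings, the oxygenation gain, the nine damage
constants, and the death threshold) and 4 local-fit (activation scale,
trauma decay rate, IL-6 production scale, wound bleed scale). The human
re-tuning stage may open only the NO-pathway and damage/death globals, fits
only O2Sat, MAP, platelets, and time of death/survival, and asserts that
every other global is bit-identical before and after.

## Synthetic cohorts

The porcine generator draws local parameters uniformly from the reference
ranges, randomizes animals to the two fit arms, and samples the nine fit
analytes at (0, 25, 85, 95, then every 30 min to 330) — baseline,
post-hemorrhage, post-dilution, post-liver-injury, and the monitoring
grid; the exact experimental schedule is not published, so this grid is the
package's documented default. The human generator fills survivor and
non-survivor quotas by rejection: candidates are drawn severity-stratified
(non-survivor candidates get higher ISS, wound-bleed scales in the upper
half of the local range, and trauma decay in the lower half), simulated,
and labeled by the simulation's own death event — so the requested
mortality fraction is met exactly by construction and labels are never
assigned. Noise is multiplicative log-normal for concentrations and counts
(positivity) and additive Gaussian (5 mmHg at the default 5% level) for
blood pressure.

What the generators do *not* emulate: assay detection limits and batch
effects, PROMMTT demographics beyond ISS and timing, missing-not-at-random
structure (the `degrade` operator drops rows independently), and
co-interventions (surgery, medications) that move BP in real records.
Passing recovery tests therefore demonstrates that the calibration
machinery inverts the model's own data manifold under sparse, noisy
sampling — not that the model family is identifiable on real cohorts.

## Virtual populations and experiments

Virtual porcine arms sample locals uniformly from the reference ranges,
100 members per arm, with member-level common random numbers across the
seven arms so contrasts are paired; infusion volumes are sampled from a
fitted-range constant (1,000–1,400 mL), not recomputed from each subject's
blood volume. One plasma unit is 300 mL; equal-volume plasma replacement is
1,250 mL. Members are forward simulations, not fits, so heuristic
plausibility is not enforced on them. "Survival time" for virtual animals
is the last time alive within the monitoring window (the porcine stage fits
no death, but the damage integral can cross the threshold for unfavorable
parameter draws). The five human experiments share each patient's
parameters and differ only in schedule; percent deltas are computed against
the same patient's baseline trajectory and reported split by baseline
survivor status.

## Problem sizes and numerical budgets

One porcine protocol run integrates ~44 stiff ODEs over 340 min in ~0.1 s,
including the controlled-bleed tuning. The shipped experiments use: 7×100
forward runs for the virtual trial; 6 subjects × 28 particles × 6
generations (plus a final evaluation) for the recovery experiment at a
relaxed tolerance (rtol 1e−5); 50 analytic candidate trajectories for the
heuristic-ceiling sweep. These sizes were chosen as the smallest designs
that exercise every code path with stable statistics.

## Known limitations

No neuroendocrine response, no gut/large endothelial surfaces, no immune
memory, no spatial resolution within compartments, no temperature state,
no individual factor kinetics (the cascade is lumped pro/anti), no
operative hemostasis, tranexamic acid, prothrombin complex concentrate, or
whole blood. RBC mass is an observable only by default (it does not feed
oxygen delivery or damage); the coupling point exists but is deliberately
left off. Parameter defaults are non-canonical design choices satisfying
steady-state and plausibility constraints, not fitted values; absolute cell
and EC units are arbitrary. Model non-identifiability is not analyzed —
the fitter returns a point estimate, not a posterior.
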