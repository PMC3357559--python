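# Methods

## Model structure and assumptions

The engine is a whole-body perfusion-limited toxicokinetic model with
eight compartments: arterial blood, venous blood, liver, kidney, skin,
fat, richly perfused and slowly perfused tissue.  Distribution into every
tissue is flow-limited, i.e. the blood leaving a tissue is in partition
equilibrium with it (`C_out = C_t / P_t`); diffusion-limited uptake,
protein binding and enterohepatic recirculation are not modelled.  The
lung is an instantaneous venous→arterial transfer with no elimination.
Blood and tissue density are taken as 1 kg/L, so µg/L, ng/mL, pg/g and
µg/kg tissue are numerically interchangeable; all internal state is in µg
and µg/L, time in hours.

Absorption is route-specific:

* **Oral** — the absorbed fraction F of each dose enters a gut depot and
  transfers first order (`k_a = ln 2 / t_half`) to the liver, emulating
  portal delivery; orally absorbed chemical therefore undergoes hepatic
  first pass before reaching the systemic circulation.
* **Dietary** — the daily dose is delivered into the gut depot at zero
  order over a feeding window (default 12 h/day) and then follows the
  oral path.
* **Dermal** — the absorbed fraction enters a skin surface depot and
  transfers first order directly into venous blood.  Cutaneous first-pass
  metabolism is neglected, and the depot feeds blood rather than the skin
  tissue compartment; the skin compartment itself only exchanges with
  arterial blood like any other tissue.

The unabsorbed fraction (1 − F) never enters the system.  Hepatic
elimination is the only loss process: one or more Michaelis–Menten
pathways act on the venous-liver concentration `C_vl = C_liver/P_liver`.
Metabolized amounts accrue to per-conjugate ledgers and are booked
directly as urinary-excreted conjugate — there is no conjugate kinetics
and no deconjugation, so a cumulative urinary conjugate fraction equals
the metabolic pathway fraction.  This also means simulated "urinary
excretion" has no renal delay; see the estimator notes below.

## Parameters

Physiology and chemical parameters live in versioned YAML files under
`src/pbtk/data/`, overridable per run.

**Physiology** (`physiology.yaml`).  The adult human (70 kg, cardiac
output 390 L/h, liver flow fraction 0.225) follows standard reference-man
conventions.  Paediatric body weights are 3.5/6/7.5/11 kg at
newborn/3 mo/6 mo/18 mo with cardiac output scaled allometrically
(BW^0.75) and the newborn liver at 0.034 kg per kg body weight — 1.3×
the adult's 0.026 kg/kg, reflecting the relatively large infant liver.
Flow fractions are held at the adult pattern across ages; with hepatic
elimination only, the steady-state blood concentration is insensitive to
the flow split (see "Calibration"), so age differences are carried by
body weight, liver mass and enzyme ontogeny.  Profiles are validated on
every load: volumes must fit in the body weight (within 5%) and
perfused-tissue flow fractions must sum to exactly 1.

**Ontogeny.**  Glucuronidation (UGT2B15, maturation proxied by the
homologous UGT2B7) is 0.10 of adult capacity at birth; sulfation
(SULT1A1) is mature from birth (factor 1.0 at all ages).  The
intermediate glucuronidation factors (0.393 at 3 mo, 0.804 at 6 mo, 1.0
at 18 mo) are obtained by inverting the urinary sulfate-fraction relation
`f = 15(1 − s)/(85 s)` at the observed sulfate shares s = 0.31, 0.18 and
0.15; the inversion is kept as a test oracle.  A missing ontogeny entry
is an error, never a silent 1.0.

**Bisphenol A** (`bpa_human.yaml`).  Two parallel conjugation pathways
with the adult clearance split 85:15 (glucuronide:sulfate).  Km is set to
5000 µg/L — far above consumer-exposure blood levels, keeping the model
linear where it is used.  Oral absorption: F = 0.9, half-life 15 min;
dermal: half-life 8 h, extent 10/13/46/60% depending on the source, with
60% as the headline value.  Partition coefficients are declared defaults
of rat-derived magnitude for a moderately lipophilic phenol.

**Calibration.**  The adult whole-liver Vmax values are not taken from
literature but calibrated: with hepatic-only elimination and no lung
loss, the period-average venous concentration at a periodic steady state
equals the average absorbed input rate divided by the total intrinsic
clearance, exactly and independently of flows and partitions.  Total
CL_int is therefore set in closed form so that the adult steady-state
blood concentration at 50 µg/kg/day oral equals 0.13 ng/mL
(CL_int = 0.9 × 50 × 70/24/0.13 ≈ 1010 L/h), then split 85:15 and
converted to Vmax = split × CL_int × Km.  Linearity makes the SSC at
11 µg/kg/day equal 0.13 × 11/50 = 0.0286 ng/mL by construction; the test
suite verifies both by simulation.  Ages scale Vmax by liver mass and the
ontogeny factor.

**Coumarin** (`coumarin_human.yaml`, `coumarin_rat.yaml`).  One
saturable pathway (CYP2A6-type 7-hydroxylation).  The human fixture uses
CL_int = 123 L/h (hepatic extraction ≈ 0.58 at a liver blood flow of
87.75 L/h — the high-first-pass behaviour characteristic of coumarin)
with Km = 10 mg/L so the 0.1 mg/kg dose regime stays linear.  The rat
fixture (0.25 kg, cardiac output 5.4 L/h, liver flow fraction 0.183) uses
whole-liver Vmax = 25 mg/h and Km = 2 mg/L: the highest chronic doses
(hundreds of mg/kg/day) then saturate metabolism transiently while the
lowest stay linear, and daily capacity exceeds the highest daily dose
even under a 50% Vmax perturbation, so a periodic steady state always
exists for the packaged study designs.  Oral/gavage absorption half-life
is 20 min, human dermal 30 min (or 960 min for slow-releasing
preparations), all with complete absorption.

All partition and rate constants for both chemicals are declared package
defaults, not literature assertions; the analyses built on them are
structural (orderings, ratios, invariances) rather than absolute
concentration predictions.

## Dose metrics and window conventions

Repeated-dose scenarios are integrated day by day until the 24-h venous
blood AUC changes by less than 1e-4 (relative) between consecutive days
(max 60 days); metrics are then taken over the converged day: Cmax, 24-h
AUC, and the SSC as AUC/24.  Single-dose scenarios report AUC(0→∞) as
the trapezoidal integral plus a terminal log-linear tail fitted to the
last tenth of the horizon; the horizon must be long enough that the tail
contributes < 0.1%, otherwise an error asks for a longer simulation.
Pathway fractions divide each conjugate's cumulative amount by the
absorbed amount and require either a periodic day (increments) or
essentially complete absorption (depot residual < 0.1% of input).

Whole-study rat liver AUC is the converged daily AUC times the study
duration in days.  This accumulation rule is exact once the daily profile
is periodic and is checked against a brute-force 28-day simulation.

## Reverse dosimetry

The dermal dose behind a measured blood concentration is reconstructed by
linear scaling of the dermal-route daily blood Cmax per unit dose:
`dose = (measured − oral background Cmax) × ref_dose / ref_Cmax`.
Matching a spot measurement to the *daily peak* of the dermal profile is
deliberately worst-case (any other time of day would need a larger dose).
Two caveats are documented rather than hidden: the inversion itself is
exactly linear (the dermal blood Cmax per unit dose is constant to
<0.1% across the linear regime, verified at three dose levels), but the
peak of a combined oral+dermal simulation is smaller than the sum of the
two route peaks because the daily maxima do not coincide; route profiles
superpose pointwise to <1e-5.  The self-consistency test therefore checks
the linear inversion and pointwise superposition, not peak additivity.

## Dose-metric identification

The question "does severity track liver Cmax or liver AUC?" is
operationalized as tie-aware rank association: Kendall tau-b between each
candidate metric (log10 scale; the log affects only the emitted scatter,
not the ranks) and the ordinal severity grade, plus a count of strict
pairwise ordering violations.  The metric with the higher tau is
selected.  At least 5 records spanning at least 3 distinct grades are
required; all-equal grades are a hard error.  The packaged surrogate
study table (`tox_studies_synthetic.csv` — a synthetic stand-in, as the
underlying literature set is not redistributable) spans 2.3–535 mg/kg/day
and 4–104 weeks over 11 studies / 31 dose groups, with grades generated
from the rat model's own liver Cmax so the packaged example exhibits the
Cmax-driven pattern.  The selection is required to be invariant to ±50%
perturbation of the rat Vmax, since ranks, not absolute scale, drive it.

## Synthetic data: what it does and does not emulate

Concentration observations get i.i.d. multiplicative lognormal noise
(unit mean, configurable CV, default 0.1) — kinetic data are positive and
CV-stable.  Synthetic toxicity study sets sample doses and durations
log-uniformly over the default ranges above, draw dietary/gavage
administration 50:50 per study, compute the driving metric through the
rat model, and grade it with a deterministic threshold rule
`clamp(floor(a·log10(metric/θ)), 0, 4)` (θ and a default to spreading the
sampled metric range evenly over the five grades) followed by ±1 label
flips with probability `noise_p` (default 0.1).  All generators are pure
functions of configuration and seed.

What passing the recovery experiments shows is that the association
statistic can tell a Cmax-driven from an AUC-driven grading mechanism
under this noise model at the packaged study-design sizes (31 dose
groups).  It does not show robustness to inter-individual variability,
to correlated grading errors, to ordinal-logistic response mechanisms, or
to dose–duration confounding stronger than log-uniform sampling produces
— none of which are modelled.

The cumulative-urinary absorption-rate estimator fits the reduced chain
gut →(ka) body →(ke) urine by least squares (SciPy `curve_fit`), with ke
fixed at a fixture value or co-estimated.  Because the full model books
conjugates into urine instantly, its cumulative output corresponds to the
reduced model's fast-elimination limit; fitting full-model output with a
fast fixture ke recovers the absorption half-life to within ~10%, which
is also the realistic precision of this estimator on real urine data.

## Numerics

LSODA with rtol 1e-8 and atol 1e-10 µg/L on a fixed 0.01 h output grid —
fine enough to capture peaks from 15-min absorption half-lives.  Days are
integrated piecewise between dose events; bolus doses are state jumps at
segment boundaries, and the boundary sample carries the post-dose state.
Concentrations more than 1e-6 µg/L below zero abort the run; smaller
negative excursions are clipped.  Every pipeline passes each run through
the mass-balance gate (< 1e-6 relative for the default tolerances;
< 1e-5 for the batch settings below).  Batch rat simulations use a
coarser, faster setting (rtol 1e-7, atol 1e-9, grid 0.02 h) — rank-based
analyses do not need the last three digits of Cmax.  Problem sizes for
the seeded experiments: 50 seeds for absorption-half-life recovery at
CV = 0.1, and 100 study sets of 31 records per generating mechanism for
dose-metric identification.

## Known limitations

* Absolute concentrations depend on declared default partitions and
  physiology; only the calibrated BPA anchor (and everything linear in
  it) is tied to a published value.
* No population variability or parameter uncertainty propagation.
* No deconjugation, conjugate kinetics, renal excretion delay, or
  protein binding; "urinary excretion" is instantaneous metabolism.
* Dietary intake is a fixed 12-h zero-order window, not a feeding model.
* The dermal depot does not interact with the skin tissue compartment,
  so skin concentrations reflect systemic redistribution only.
* Human age groups are discrete; no continuous growth, no paediatric rat.
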