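# pbtk — physiologically based toxicokinetic modelling for risk assessment

`pbtk` is a Python toolkit for the internal-dose questions that come up in
regulatory risk assessment of consumer chemicals: *what blood and organ
concentrations does an external exposure produce, how do they change with
age, with the route of exposure (oral, dietary, dermal), and which kinetic
metric — peak concentration or cumulative exposure — actually drives the
toxicity?*  It is aimed at toxicologists and exposure scientists who need a
transparent, fully scriptable alternative to closed PBPK tools.

## The model

The core is a perfusion-limited compartmental ODE model.  Each non-blood
tissue *t* (liver, kidney, skin, fat, richly and slowly perfused tissue)
obeys

```
V_t dC_t/dt = Q_t (C_art − C_t / P_t)
```

with tissue volume `V_t` (L), blood flow `Q_t` (L/h) and tissue:blood
partition coefficient `P_t`.  Venous blood collects the tissue outflows,
and the lung is an instantaneous venous→arterial transfer.  Orally or
dietarily absorbed chemical leaves a gut depot first order (`k_a = ln 2 /
t_half`) straight into the liver (portal delivery), so it is subject to
hepatic first pass; dermally absorbed chemical leaves a skin surface depot
into venous blood.  The liver eliminates via one or more saturable
pathways,

```
rate_j = Vmax_j · C_vl / (Km_j + C_vl),   C_vl = C_liver / P_liver,
```

with metabolized amounts booked per conjugate as urinary-excreted.  Every
run is audited by a mass-balance gate (input = depots + body burden +
metabolized, to better than 1e-6 relative).

On top of the engine sit:

* **Age scaling** — physiology profiles for the human newborn, 3-, 6- and
  18-month-old and adult (plus the adult rat), and enzyme-ontogeny factors
  that scale adult Vmax (e.g. glucuronidation at 10% of adult capacity in
  the newborn, sulfation already mature at birth).
* **Dose metrics** — Cmax, windowed and extrapolated AUC, the 24-h average
  steady-state concentration (SSC) under repeated daily dosing, conjugate
  pathway fractions, percent-of-reference and fold ratios.
* **Case pipelines** — bisphenol A in the bottle-fed newborn
  (`pbtk.cases.bpa_newborn`), oral-vs-dermal BPA with reverse dosimetry
  (`pbtk.cases.bpa_dermal`), and coumarin route comparison with
  Cmax-vs-AUC dose-metric identification from graded rat hepatotoxicity
  (`pbtk.cases.coumarin`).
* **Synthetic data** — noisy kinetic profiles, cumulative urinary-excretion
  series with a matching absorption-half-life estimator, and
  ground-truth-labelled toxicity study sets for recovery experiments
  (`pbtk.synthetic`).

## Worked example

Steady-state blood concentrations of bisphenol A for the bottle-fed
newborn (11 µg/kg/day, six feeds) against the adult at the same dose and
at the tolerable daily intake (50 µg/kg/day, three portions):

```python
from pbtk.cases import bpa_newborn

report = bpa_newborn.run_case()
print(report.table1a.round(4).to_string(index=False))
```

```
age_group  dose_ug_per_kg_day  ssc_ng_per_mL  percent_of_tdi_ssc  fold_vs_adult
  newborn                11.0         0.0931             71.5808         3.2543
    adult                11.0         0.0286             21.9955            NaN
    adult                50.0         0.1300            100.0000            NaN
```

The adult at the TDI sits at 0.13 ng/mL (the calibration anchor of the
shipped BPA parameter set).  The newborn's immature glucuronidation raises
its blood level 3.3-fold over an adult at the same per-kg dose, to ~72% of
the TDI-referenced concentration — close to, but not exceeding, the adult
internal exposure at the TDI.  The conjugate split shifts with age from
sulfate-dominated (64%/36% in the newborn) to the mature 15%/85% pattern:

```
age_group  sulfate_percent  glucuronide_percent
  newborn             63.8                 36.2
      3mo             31.0                 69.0
      6mo             18.0                 82.0
     18mo             15.0                 85.0
    adult             15.0                 85.0
```

The same pipelines are available from the shell:

```bash
pbtk case bpa-newborn --out out/newborn
pbtk case bpa-dermal  --out out/dermal
pbtk case coumarin    --out out/coumarin --figure
pbtk synth toxstudies --mechanism cmax_driven --seed 1 --out out/synth
```

## Layout

```
src/pbtk/
  physiology.py   profiles + ontogeny        core.py       ODE engine
  metrics.py      dose metrics               chemicals.py  fixtures/scenarios
  cases/          the three pipelines        synthetic.py  generators + estimator
  cli.py          command line               data/         versioned parameter files
```

See `docs/methods.md` for the model assumptions, parameter provenance,
numerical settings and known limitations.
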