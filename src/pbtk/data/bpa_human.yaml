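# Bisphenol A, human model defaults.
#
# Partition coefficients are declared defaults (rat-derived order of
# magnitude, moderately lipophilic phenol).  Hepatic metabolism is two
# parallel conjugation pathways; whole-liver adult Vmax is obtained by
# calibrating total intrinsic clearance so that the adult steady-state
# blood concentration at the anchor oral dose equals the anchor value,
# with the stated glucuronide:sulfate clearance split.  Km is set well
# above consumer-exposure concentrations (linear regime).
chemical: bisphenol_a
species: human
partitions:
  liver: 1.5
  kidney: 1.3
  skin: 2.0
  fat: 5.0
  richly_perfused: 1.5
  slowly_perfused: 1.0
pathways:
  - {name: glucuronidation, conjugate: glucuronide, clearance_split: 0.85, km_ug_per_L: 5000.0}
  - {name: sulfation,       conjugate: sulfate,     clearance_split: 0.15, km_ug_per_L: 5000.0}
calibration:
  ssc_anchor_ng_per_mL: 0.13
  anchor_dose_ug_per_kg_day: 50.0
  anchor_absorbed_fraction: 0.9
absorption:
  oral_absorbed_fraction: 0.9
  oral_half_life_h: 0.25
  dermal_half_life_h: 8.0
  dermal_extents: [0.10, 0.13, 0.46, 0.60]
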