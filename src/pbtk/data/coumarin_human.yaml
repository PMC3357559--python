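# Coumarin, human model defaults.
#
# A single saturable hepatic pathway (CYP2A6 7-hydroxylation).  Declared
# defaults: intrinsic clearance 123 L/h gives the high-first-pass
# behaviour characteristic of coumarin (hepatic extraction ~0.58 at a
# liver blood flow of 87.75 L/h); Km is set high enough that a 0.1 mg/kg
# dose stays in the linear regime.  Partition coefficients are calculated
# values for a lipophilic lactone.
chemical: coumarin
species: human
partitions:
  liver: 2.0
  kidney: 1.5
  skin: 2.0
  fat: 10.0
  richly_perfused: 2.0
  slowly_perfused: 1.5
pathways:
  - {name: coumarin_7_hydroxylation, conjugate: hydroxycoumarin,
     vmax_ug_per_h: 1230000.0, km_ug_per_L: 10000.0}
absorption:
  oral_half_life_h: 0.3333333333333333     # 20 min
  dermal_half_life_h: 0.5                  # 30 min
  dermal_slow_half_life_h: 16.0            # 960 min
  absorbed_fraction: 1.0
tdi_mg_per_kg_day: 0.1
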