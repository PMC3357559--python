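# Coumarin, rat model defaults.
#
# Declared defaults sized so that the highest dietary/gavage doses used
# in chronic rat studies (hundreds of mg/kg/day) saturate hepatic
# metabolism transiently while the lowest doses remain linear, and so
# that daily capacity exceeds the highest daily dose even under a 50%
# Vmax perturbation: whole-liver Vmax 25 mg/h, Km 2 mg/L.  Gavage is a daily bolus (oral absorption
# half-life 20 min); dietary dosing delivers the daily dose into the gut
# at zero order over 12 h (the active feeding period).
chemical: coumarin
species: rat
partitions:
  liver: 2.0
  kidney: 1.5
  skin: 2.0
  fat: 10.0
  richly_perfused: 2.0
  slowly_perfused: 1.5
pathways:
  - {name: coumarin_7_hydroxylation, conjugate: hydroxycoumarin,
     vmax_ug_per_h: 25000.0, km_ug_per_L: 2000.0}
absorption:
  oral_half_life_h: 0.3333333333333333     # 20 min
  absorbed_fraction: 1.0
  dietary_duration_h: 12.0
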