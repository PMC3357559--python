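# Default physiology and enzyme-ontogeny tables.
#
# Volumes are fractions of body weight (tissue density 1 kg/L), flows are
# fractions of cardiac output; perfused-tissue flow fractions sum to 1.
# Blood compartments carry no flow fraction.  Human adult values follow
# standard reference-man conventions; paediatric organ fractions and
# cardiac outputs are allometric/plausible stand-ins (see docs/methods.md).
human:
  adult:
    body_weight_kg: 70.0
    cardiac_output_L_per_h: 390.0
    tissues:
      liver:            {volume_fraction: 0.026,  flow_fraction: 0.225}
      kidney:           {volume_fraction: 0.004,  flow_fraction: 0.190}
      skin:             {volume_fraction: 0.037,  flow_fraction: 0.058}
      fat:              {volume_fraction: 0.190,  flow_fraction: 0.050}
      richly_perfused:  {volume_fraction: 0.050,  flow_fraction: 0.227}
      slowly_perfused:  {volume_fraction: 0.550,  flow_fraction: 0.250}
      arterial_blood:   {volume_fraction: 0.0257}
      venous_blood:     {volume_fraction: 0.0514}
  newborn:
    body_weight_kg: 3.5
    cardiac_output_L_per_h: 41.2
    tissues:
      liver:            {volume_fraction: 0.034,  flow_fraction: 0.225}
      kidney:           {volume_fraction: 0.007,  flow_fraction: 0.190}
      skin:             {volume_fraction: 0.050,  flow_fraction: 0.058}
      fat:              {volume_fraction: 0.130,  flow_fraction: 0.050}
      richly_perfused:  {volume_fraction: 0.060,  flow_fraction: 0.227}
      slowly_perfused:  {volume_fraction: 0.500,  flow_fraction: 0.250}
      arterial_blood:   {volume_fraction: 0.027}
      venous_blood:     {volume_fraction: 0.053}
  3mo:
    body_weight_kg: 6.0
    cardiac_output_L_per_h: 61.8
    tissues:
      liver:            {volume_fraction: 0.032,  flow_fraction: 0.225}
      kidney:           {volume_fraction: 0.0065, flow_fraction: 0.190}
      skin:             {volume_fraction: 0.048,  flow_fraction: 0.058}
      fat:              {volume_fraction: 0.180,  flow_fraction: 0.050}
      richly_perfused:  {volume_fraction: 0.058,  flow_fraction: 0.227}
      slowly_perfused:  {volume_fraction: 0.480,  flow_fraction: 0.250}
      arterial_blood:   {volume_fraction: 0.027}
      venous_blood:     {volume_fraction: 0.053}
  6mo:
    body_weight_kg: 7.5
    cardiac_output_L_per_h: 73.0
    tissues:
      liver:            {volume_fraction: 0.030,  flow_fraction: 0.225}
      kidney:           {volume_fraction: 0.006,  flow_fraction: 0.190}
      skin:             {volume_fraction: 0.046,  flow_fraction: 0.058}
      fat:              {volume_fraction: 0.200,  flow_fraction: 0.050}
      richly_perfused:  {volume_fraction: 0.056,  flow_fraction: 0.227}
      slowly_perfused:  {volume_fraction: 0.470,  flow_fraction: 0.250}
      arterial_blood:   {volume_fraction: 0.027}
      venous_blood:     {volume_fraction: 0.053}
  18mo:
    body_weight_kg: 11.0
    cardiac_output_L_per_h: 97.4
    tissues:
      liver:            {volume_fraction: 0.028,  flow_fraction: 0.225}
      kidney:           {volume_fraction: 0.0055, flow_fraction: 0.190}
      skin:             {volume_fraction: 0.043,  flow_fraction: 0.058}
      fat:              {volume_fraction: 0.200,  flow_fraction: 0.050}
      richly_perfused:  {volume_fraction: 0.054,  flow_fraction: 0.227}
      slowly_perfused:  {volume_fraction: 0.490,  flow_fraction: 0.250}
      arterial_blood:   {volume_fraction: 0.027}
      venous_blood:     {volume_fraction: 0.053}
rat:
  adult:
    body_weight_kg: 0.25
    cardiac_output_L_per_h: 5.4
    tissues:
      liver:            {volume_fraction: 0.0366, flow_fraction: 0.183}
      kidney:           {volume_fraction: 0.0073, flow_fraction: 0.141}
      skin:             {volume_fraction: 0.190,  flow_fraction: 0.058}
      fat:              {volume_fraction: 0.070,  flow_fraction: 0.070}
      richly_perfused:  {volume_fraction: 0.050,  flow_fraction: 0.248}
      slowly_perfused:  {volume_fraction: 0.550,  flow_fraction: 0.300}
      arterial_blood:   {volume_fraction: 0.027}
      venous_blood:     {volume_fraction: 0.047}

# Fraction of adult enzyme activity by age group (multiplies adult Vmax).
# Glucuronidation (UGT2B15 proxied by UGT2B7 maturation): <10% of adult
# capacity at birth, maturing over the first 18 months.  Sulfation
# (SULT1A1) is already at adult levels in utero.
ontogeny:
  glucuronidation: {newborn: 0.10, 3mo: 0.393, 6mo: 0.804, 18mo: 1.0, adult: 1.0}
  sulfation:       {newborn: 1.0,  3mo: 1.0,   6mo: 1.0,   18mo: 1.0, adult: 1.0}
  coumarin_7_hydroxylation: {adult: 1.0}
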