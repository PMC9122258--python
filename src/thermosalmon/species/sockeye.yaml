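# Juvenile sockeye salmon (Oncorhynchus nerka).
# Allometry and activity model after Beauchamp et al. (1989); temperature
# anchors are approximate transcriptions. Used for qualitative growth-curve
# comparisons only (sockeye use the study reach for migration, not rearing).
species: sockeye
common_name: sockeye salmon
consumption:
  form: thornton_lessem
  CA: 0.303
  CB: -0.275
  CQ: 4.0
  CTO: 15.0
  CTM: 18.0
  CTL: 24.0
  CK1: 0.36
  CK4: 0.01
respiration:
  form: swim_speed
  RA: 0.00264
  RB: -0.217
  RQ: 0.06818
  RTO: 0.0234
  RTL: 25.0
  RK1: 1.0
  RK4: 0.13
  ACT: 9.7
  BACT: 0.0405
waste:
  egestion_form: indigestible
  FA: 0.212
  FB: -0.222
  FG: 0.631
  excretion_form: elliott
  UA: 0.0314
  UB: 0.58
  UG: -0.299
  indigestible_fraction: 0.075
sda_coeff: 0.172
oxycal: 13560.0
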