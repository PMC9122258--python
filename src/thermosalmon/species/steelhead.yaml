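# Juvenile steelhead / rainbow trout (Oncorhynchus mykiss).
# Allometry (CA, CB) after Rand et al. (1993); the temperature-dependence
# anchors are approximate transcriptions reflecting the species' documented
# higher thermal tolerance relative to Chinook (warmer optimum and upper
# limit). Respiration assumed equal to the Stewart & Ibarra salmonid form.
# Used for qualitative growth-curve comparisons only.
species: steelhead
common_name: steelhead trout
consumption:
  form: thornton_lessem
  CA: 0.398
  CB: -0.3
  CQ: 5.0
  CTO: 18.0
  CTM: 22.0
  CTL: 27.0
  CK1: 0.25
  CK4: 0.3
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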