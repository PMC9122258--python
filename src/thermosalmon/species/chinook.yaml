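# Juvenile Chinook salmon (Oncorhynchus tshawytscha).
#
# Provenance:
#   consumption  — allometry (CA, CB) from Stewart & Ibarra (1991); the
#                  Thornton-Lessem temperature dependence uses the juvenile
#                  re-fit of Plumb & Moffitt (2015), as shipped with Fish
#                  Bioenergetics 4.0.
#   respiration  — Stewart & Ibarra (1991) swimming-speed activity form.
#   waste        — Elliott-type egestion/excretion with the indigestible-prey
#                  correction (Stewart et al. 1983 formulation).
#   indigestible_fraction — diet property (share of prey mass that is
#                  indigestible), a required model input that the source
#                  study does not print; 0.075 is within the range commonly
#                  assumed for aquatic-insect diets (0-0.17) and was fixed by
#                  matching the two published zero-growth temperatures
#                  (18.9 degC at p=0.5, 22.7 degC at p=0.9).
species: chinook
common_name: Chinook salmon
consumption:
  form: thornton_lessem
  CA: 0.303        # g/g/d intercept
  CB: -0.275       # mass exponent
  CQ: 4.97         # lower anchor temperature, degC
  CTO: 20.93       # upper end of rising limb, degC
  CTM: 20.93       # start of falling limb, degC
  CTL: 24.05       # upper anchor temperature, degC
  CK1: 0.36        # proportion of Cmax at CQ
  CK4: 0.53        # proportion of Cmax at CTL
respiration:
  form: swim_speed
  RA: 0.00264      # g O2/g/d intercept
  RB: -0.217       # mass exponent
  RQ: 0.06818      # temperature coefficient (1/degC)
  RTO: 0.0234      # swimming-speed coefficient (s/cm)
  RTL: 25.0        # cutoff temperature for the speed function, degC
  RK1: 1.0         # speed intercept above RTL
  RK4: 0.13        # speed mass exponent
  ACT: 9.7         # speed intercept below RTL (cm/s)
  BACT: 0.0405     # speed temperature coefficient (1/degC)
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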