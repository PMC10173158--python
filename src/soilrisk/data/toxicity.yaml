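# Default per-metal toxicity screening values for the soil exposure pathways.
#
# RfD_ing / RfD_inh / RfD_derm: reference doses, mg/(kg day).
# SF_ing: oral carcinogenic slope factor, (mg/(kg day))^-1.
# carcinogen: whether the metal enters the incremental lifetime cancer risk.
#
# These are USEPA IRIS-style screening values commonly used for residential
# soil assessments.  They are defaults, not site law: override any entry via
# the toxicity config.  Dermal RfDs are oral RfDs scaled by gastrointestinal
# absorption.  Magnesium is an essential macro-element with no established
# soil toxicity criteria, so it ships with neither an RfD nor a slope factor
# and is excluded (with a warning) from hazard and cancer totals.
As:
  RfD_ing: 3.0e-4
  RfD_inh: 3.01e-4
  RfD_derm: 1.23e-4
  SF_ing: 1.5
  carcinogen: true
Cd:
  RfD_ing: 1.0e-3
  RfD_inh: 1.0e-3
  RfD_derm: 1.0e-5
  SF_ing: 6.1
  carcinogen: true
Cr:
  RfD_ing: 3.0e-3
  RfD_inh: 2.86e-5
  RfD_derm: 6.0e-5
  SF_ing: 0.5
  carcinogen: true
Cu:
  RfD_ing: 4.0e-2
  RfD_inh: 4.02e-2
  RfD_derm: 1.2e-2
Fe:
  RfD_ing: 7.0e-1
  RfD_inh: 7.0e-1
  RfD_derm: 1.4e-1
Mg: {}
Mn:
  RfD_ing: 4.6e-2
  RfD_inh: 1.43e-5
  RfD_derm: 1.84e-3
Ni:
  RfD_ing: 2.0e-2
  RfD_inh: 2.06e-2
  RfD_derm: 5.4e-3
  SF_ing: 1.7
  carcinogen: true
Pb:
  RfD_ing: 3.5e-3
  RfD_inh: 3.52e-3
  RfD_derm: 5.25e-4
  SF_ing: 8.5e-3
  carcinogen: true
Zn:
  RfD_ing: 3.0e-1
  RfD_inh: 3.0e-1
  RfD_derm: 6.0e-2
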