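# Default calibration, version 1.
#
# Kinetics: the dose-response saturates by ~1 uM IPTG; induction reaches
# 95% of target and decay falls to 5% residual by 6 h (k = ln(20)/6).
#
# PK rates are set from closed-form decay arithmetic against the in-vivo
# landmarks: an unprotected strain falls below the blood LOD (~400 CFU
# total at 200 CFU/ml in ~2 ml mouse blood) within 0.5 h of a 5e6 CFU
# i.v. dose, while a fully encapsulated strain stays detectable through
# ~4 h; a transiently encapsulated strain beats both static and bare
# strains on 72-h tumor specificity.
kinetics:
  ec50: 0.1          # uM
  hill_n: 2.0
  k_on: 0.49928871225899846   # 1/h, ln(20)/6
  k_off: 0.49928871225899846  # 1/h
  basal: 0.0
pk:
  k_clear: 20.0      # 1/h baseline blood immune clearance
  p_min: 0.1         # clearance multiplier at full CAP
  k_mps: 0.25        # 1/h blood -> liver/spleen uptake
  delta_p: 0.3       # 1/h peripheral elimination at zero CAP
  k_entry: 0.03      # 1/h blood -> tumor seeding, per tumor
  k_escape: 0.0      # 1/h tumor -> blood escape; negligible after i.v.
                     # delivery, set positive for intratumoral
                     # translocation studies (pipeline uses 0.01)
  r_t: 0.1           # 1/h intratumoral growth
  cap_k: 1.0e+9      # CFU tumor carrying capacity
  n_tumors: 2
scenario:
  route: iv
  dose: 5.0e+6       # CFU, the matched biodistribution dose
  cap_mode: transient
  horizon: 72.0      # h
  treated_tumor: 0
  induction_start_h: 24.0   # in-situ: IPTG water from day 1 after injection
  induction_iptg: 10000.0   # uM, saturating (10 mM drinking water)
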