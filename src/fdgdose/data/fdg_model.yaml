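# Revised whole-body compartmental model for 2-[18F]FDG.
# Transfer coefficients in h^-1, stored at the published printed precision.
# Blood plasma is the central exchange compartment receiving the bolus;
# "Other" is a generic two-pool region for tissues not modelled explicitly;
# urinary excretion runs plasma -> kidneys -> bladder contents (terminal
# here; voiding is handled by the dynamic bladder module).
compartments:
  - Blood 1
  - Blood 2
  - Brain
  - Lungs
  - Liver
  - Heart wall 1
  - Heart wall 2
  - Kidneys
  - Pancreas
  - Spleen
  - Other 1
  - Other 2
  - UB contents
transfers:
  - {from: Blood 1, to: Blood 2, rate_per_h: 201.0}
  - {from: Blood 1, to: Brain, rate_per_h: 1.12}
  - {from: Blood 1, to: Lungs, rate_per_h: 0.43}
  - {from: Blood 1, to: Liver, rate_per_h: 8.08}
  - {from: Blood 1, to: Heart wall 1, rate_per_h: 1.19}
  - {from: Blood 1, to: Other 1, rate_per_h: 25.4}
  - {from: Blood 1, to: Kidneys, rate_per_h: 1.32}
  - {from: Blood 1, to: Pancreas, rate_per_h: 0.39}
  - {from: Blood 1, to: Spleen, rate_per_h: 0.28}
  - {from: Blood 2, to: Blood 1, rate_per_h: 441.0}
  - {from: Brain, to: Blood 1, rate_per_h: 0.80}
  - {from: Heart wall 1, to: Blood 1, rate_per_h: 2.06}
  - {from: Heart wall 1, to: Heart wall 2, rate_per_h: 0.20}
  - {from: Kidneys, to: UB contents, rate_per_h: 9.20}
  - {from: Liver, to: Blood 1, rate_per_h: 21.0}
  - {from: Lungs, to: Blood 1, rate_per_h: 9.6}
  - {from: Other 1, to: Blood 1, rate_per_h: 5.30}
  - {from: Other 1, to: Other 2, rate_per_h: 0.84}
  - {from: Other 2, to: Blood 1, rate_per_h: 0.78}
  - {from: Pancreas, to: Blood 1, rate_per_h: 11.2}
  - {from: Spleen, to: Blood 1, rate_per_h: 7.73}
injection:
  compartment: Blood 1
  amount: 1.0
urine_compartment: UB contents
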