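# Regional blood volume fractions: share of total blood residing in each
# organ, used to split a PET organ measurement into parenchyma + contained
# blood. Interpretation of ICRP Publication 89 reference regional blood
# volumes (whole blood, arterial+venous pooled); editable by the user.
organ,fraction
Brain,0.012
Lungs,0.105
Liver,0.10
Heart wall 1,0.01
Kidneys,0.02
Pancreas,0.006
Spleen,0.014
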