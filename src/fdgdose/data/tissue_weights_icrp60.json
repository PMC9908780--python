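{
  "scheme": "ICRP60",
  "weights": {
    "Gonads": 0.20,
    "Red bone marrow": 0.12,
    "Colon wall": 0.12,
    "Lungs": 0.12,
    "Stomach wall": 0.12,
    "Urinary bladder wall": 0.05,
    "Breast": 0.05,
    "Liver": 0.05,
    "Oesophagus": 0.05,
    "Thyroid": 0.05,
    "Skin": 0.01,
    "Endosteum": 0.01,
    "Remainder": 0.05
  }
}
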