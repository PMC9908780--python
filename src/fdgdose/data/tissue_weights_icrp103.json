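{
  "scheme": "ICRP103",
  "weights": {
    "Red bone marrow": 0.12,
    "Colon wall": 0.12,
    "Lungs": 0.12,
    "Stomach wall": 0.12,
    "Breast": 0.12,
    "Remainder": 0.12,
    "Gonads": 0.08,
    "Urinary bladder wall": 0.04,
    "Oesophagus": 0.04,
    "Liver": 0.04,
    "Thyroid": 0.04,
    "Endosteum": 0.01,
    "Brain": 0.01,
    "Salivary glands": 0.01,
    "Skin": 0.01
  }
}
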