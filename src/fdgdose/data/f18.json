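{
  "name": "F-18",
  "half_life_min": 109.77,
  "emissions": [
    {"type": "beta", "energy_MeV": 0.2498, "yield": 0.9673},
    {"type": "photon", "energy_MeV": 0.511, "yield": 1.9346}
  ]
}
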