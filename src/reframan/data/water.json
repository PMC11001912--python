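{
  "material": "water",
  "comment": "broad bending (1640) and OH-stretch (3200-3450) bands",
  "lines": [
    {"center_cm1": 1640.0, "rel_intensity": 8.0, "fwhm_cm1": 80.0, "shape": "gaussian"},
    {"center_cm1": 3230.0, "rel_intensity": 60.0, "fwhm_cm1": 220.0, "shape": "gaussian"},
    {"center_cm1": 3430.0, "rel_intensity": 70.0, "fwhm_cm1": 200.0, "shape": "gaussian"}
  ]
}
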