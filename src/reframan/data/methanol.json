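{
  "material": "methanol",
  "comment": "aqueous methanol bands (C-O stretch 1035, CH3 modes)",
  "lines": [
    {"center_cm1": 1035.0, "rel_intensity": 60.0, "fwhm_cm1": 14.0, "shape": "lorentzian"},
    {"center_cm1": 1453.0, "rel_intensity": 15.0, "fwhm_cm1": 18.0, "shape": "lorentzian"},
    {"center_cm1": 2836.0, "rel_intensity": 80.0, "fwhm_cm1": 18.0, "shape": "lorentzian"},
    {"center_cm1": 2945.0, "rel_intensity": 70.0, "fwhm_cm1": 20.0, "shape": "lorentzian"}
  ]
}
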