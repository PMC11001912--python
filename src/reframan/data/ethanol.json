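{
  "material": "ethanol",
  "comment": "aqueous ethanol bands (C-C-O 883, C-O 1052/1095, CH modes)",
  "lines": [
    {"center_cm1": 883.0, "rel_intensity": 70.0, "fwhm_cm1": 12.0, "shape": "lorentzian"},
    {"center_cm1": 1052.0, "rel_intensity": 30.0, "fwhm_cm1": 14.0, "shape": "lorentzian"},
    {"center_cm1": 1095.0, "rel_intensity": 25.0, "fwhm_cm1": 16.0, "shape": "lorentzian"},
    {"center_cm1": 1454.0, "rel_intensity": 25.0, "fwhm_cm1": 18.0, "shape": "lorentzian"},
    {"center_cm1": 2876.0, "rel_intensity": 60.0, "fwhm_cm1": 18.0, "shape": "lorentzian"},
    {"center_cm1": 2928.0, "rel_intensity": 85.0, "fwhm_cm1": 18.0, "shape": "lorentzian"},
    {"center_cm1": 2974.0, "rel_intensity": 55.0, "fwhm_cm1": 18.0, "shape": "lorentzian"}
  ]
}
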