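{
  "material": "toluene",
  "comment": "ASTM E1840 consensus band positions; representative areas/widths",
  "lines": [
    {"center_cm1": 521.7, "rel_intensity": 12.0, "fwhm_cm1": 5.0, "shape": "lorentzian"},
    {"center_cm1": 786.5, "rel_intensity": 55.0, "fwhm_cm1": 5.0, "shape": "lorentzian"},
    {"center_cm1": 1003.6, "rel_intensity": 100.0, "fwhm_cm1": 4.0, "shape": "lorentzian"},
    {"center_cm1": 1030.6, "rel_intensity": 28.0, "fwhm_cm1": 5.0, "shape": "lorentzian"},
    {"center_cm1": 1211.4, "rel_intensity": 18.0, "fwhm_cm1": 6.0, "shape": "lorentzian"},
    {"center_cm1": 1604.7, "rel_intensity": 22.0, "fwhm_cm1": 6.0, "shape": "lorentzian"},
    {"center_cm1": 2921.1, "rel_intensity": 40.0, "fwhm_cm1": 14.0, "shape": "lorentzian"},
    {"center_cm1": 3057.1, "rel_intensity": 60.0, "fwhm_cm1": 10.0, "shape": "lorentzian"}
  ]
}
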