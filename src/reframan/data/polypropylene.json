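{
  "material": "polypropylene",
  "comment": "representative isotactic polypropylene bands",
  "lines": [
    {"center_cm1": 398.1, "rel_intensity": 18.0, "fwhm_cm1": 6.0, "shape": "lorentzian"},
    {"center_cm1": 808.9, "rel_intensity": 55.0, "fwhm_cm1": 5.0, "shape": "lorentzian"},
    {"center_cm1": 841.4, "rel_intensity": 45.0, "fwhm_cm1": 6.0, "shape": "lorentzian"},
    {"center_cm1": 972.7, "rel_intensity": 30.0, "fwhm_cm1": 6.0, "shape": "lorentzian"},
    {"center_cm1": 998.3, "rel_intensity": 25.0, "fwhm_cm1": 6.0, "shape": "lorentzian"},
    {"center_cm1": 1151.5, "rel_intensity": 20.0, "fwhm_cm1": 7.0, "shape": "lorentzian"},
    {"center_cm1": 1219.9, "rel_intensity": 12.0, "fwhm_cm1": 7.0, "shape": "lorentzian"},
    {"center_cm1": 1329.8, "rel_intensity": 22.0, "fwhm_cm1": 8.0, "shape": "lorentzian"},
    {"center_cm1": 1458.4, "rel_intensity": 60.0, "fwhm_cm1": 9.0, "shape": "lorentzian"},
    {"center_cm1": 2883.0, "rel_intensity": 80.0, "fwhm_cm1": 14.0, "shape": "lorentzian"},
    {"center_cm1": 2952.0, "rel_intensity": 70.0, "fwhm_cm1": 14.0, "shape": "lorentzian"}
  ]
}
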