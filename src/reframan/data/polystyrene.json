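{
  "material": "polystyrene",
  "comment": "ASTM E1840 consensus band positions; relative areas and widths are representative values for the bulk polymer",
  "lines": [
    {"center_cm1": 620.9, "rel_intensity": 16.0, "fwhm_cm1": 5.0, "shape": "lorentzian"},
    {"center_cm1": 1001.4, "rel_intensity": 100.0, "fwhm_cm1": 4.0, "shape": "lorentzian"},
    {"center_cm1": 1031.8, "rel_intensity": 27.0, "fwhm_cm1": 5.0, "shape": "lorentzian"},
    {"center_cm1": 1155.3, "rel_intensity": 13.0, "fwhm_cm1": 6.0, "shape": "lorentzian"},
    {"center_cm1": 1450.5, "rel_intensity": 9.0, "fwhm_cm1": 8.0, "shape": "lorentzian"},
    {"center_cm1": 1583.1, "rel_intensity": 12.0, "fwhm_cm1": 6.0, "shape": "lorentzian"},
    {"center_cm1": 1602.3, "rel_intensity": 28.0, "fwhm_cm1": 5.0, "shape": "lorentzian"},
    {"center_cm1": 2852.4, "rel_intensity": 9.0, "fwhm_cm1": 10.0, "shape": "lorentzian"},
    {"center_cm1": 2904.5, "rel_intensity": 13.0, "fwhm_cm1": 10.0, "shape": "lorentzian"},
    {"center_cm1": 3054.3, "rel_intensity": 32.0, "fwhm_cm1": 8.0, "shape": "lorentzian"}
  ]
}
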