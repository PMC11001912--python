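{
  "material": "diamond",
  "comment": "single first-order phonon line; natural linewidth ~1.8 cm^-1",
  "lines": [
    {"center_cm1": 1332.5, "rel_intensity": 100.0, "fwhm_cm1": 1.8, "shape": "lorentzian"}
  ]
}
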