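{
  "description": "Quadrichroic chlorophyll equations for 90% acetone extracts (Ritchie 2008, Photosynthetica 46:115-126), manually transcribed. Form 'concentration_equations' stores the published matrix M with c (ug/ml) = M . OD over a 1 cm path; the E . c = OD absorption matrix is its numerical inverse. Transcription caveat: values copied by hand from the cited reference; the linear solver is independent of them and is validated with synthetic matrices.",
  "solvent": "90% acetone",
  "path_length_cm": 1.0,
  "form": "concentration_equations",
  "wavelengths_nm": [630.0, 647.0, 664.0, 691.0],
  "pigments": ["chl_a", "chl_b", "chl_c", "chl_d"],
  "coefficients": {
    "chl_a": [-0.3319, -1.7485, 11.9442, -1.4306],
    "chl_b": [-1.2825, 19.8839, -4.8860, -2.3416],
    "chl_c": [23.5902, -7.8516, -1.5214, -1.7443],
    "chl_d": [-0.5881, 0.0902, -0.1564, 11.0473]
  }
}
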