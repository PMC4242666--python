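{
  "n_residues": 60,
  "variance_A2": 1.0,
  "blocks": [
    {"set_a": [0, 1, 2, 3], "set_b": [0, 1, 2, 3], "correlation": 0.9},
    {"set_a": [24, 25, 26, 27], "set_b": [24, 25, 26, 27], "correlation": 0.9},
    {"set_a": [0, 1, 2, 3], "set_b": [24, 25, 26, 27], "correlation": -0.8}
  ]
}
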