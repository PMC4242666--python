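{
  "_comment": "EXAMPLE site definitions (synthetic indices). Residue sets are 0-based indices into the coordinate ensemble. Replace with the Ca2+-binding-site residue lists of your own structural model before use.",
  "site1": [0, 1, 2, 3],
  "site2": [12, 13, 14],
  "site3": [24, 25, 26, 27],
  "site4": [36, 37, 38],
  "site5": [48, 49, 50]
}
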