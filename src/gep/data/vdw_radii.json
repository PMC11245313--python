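{
  "comment": "van der Waals radii in Angstrom, used by the built-in surface sampler",
  "radii": {
    "H": 1.2,
    "C": 1.7,
    "N": 1.55,
    "O": 1.52,
    "S": 1.8,
    "P": 1.8,
    "SE": 1.9,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98
  },
  "default": 1.7
}
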