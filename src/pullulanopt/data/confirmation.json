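{
  "comment": "Wet-lab confirmation runs at the two recommended media (experimental inputs; not computable from the fixture).",
  "taguchi": {
    "combination": {"sucrose": 60, "K2HPO4": 4, "NaCl": 1.5, "MgSO4": 0.3,
                    "yeast_extract": 1, "pH": 5.5, "incubation_time": 48},
    "observed_mean": 7.23,
    "observed_sd": 0.13
  },
  "tree": {
    "combination": {"sucrose": 40, "K2HPO4": 4, "NaCl": 1.5, "MgSO4": 0.3,
                    "yeast_extract": 1, "pH": 5.5, "incubation_time": 48},
    "observed_mean": 7.11,
    "observed_sd": 0.07,
    "terminal_node": 7
  }
}
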