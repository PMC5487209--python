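{
  "model": "full",
  "units": {"time": "day", "concentration": "nM"},
  "params": {
    "kon": 0.592,
    "koff": 0.9,
    "kin": 2.212224,
    "kout": 0.823,
    "keL": 0.024,
    "keP": 0.201,
    "L0": 14.8148,
    "alpha": 0.1
  },
  "feedback": {"family": "mainly_linear", "h0": 2.688, "beta": 0.5}
}
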