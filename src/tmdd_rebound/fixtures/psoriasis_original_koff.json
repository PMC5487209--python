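{
  "model": "psoriasis",
  "units": {"time": "day", "drug": "ug/kg", "receptor": "%CD11a"},
  "params": {
    "ka": 0.242,
    "k10": 0.114,
    "k12": 0.097,
    "k21": 0.193,
    "k30": 0.444,
    "koff": 0.00154,
    "Vm": 26.9,
    "Vm2": 2.16,
    "Kmc": 0.033,
    "Vc": 64.3,
    "Fa": 0.564,
    "k03max": 334.0,
    "Y0": 100.0
  }
}
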