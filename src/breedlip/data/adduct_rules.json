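{
  "[M+H]1+": {"delta": {"H": 1}, "charge": 1},
  "[M+H]1+ 13C": {"delta": {"H": 1}, "charge": 1, "n_c13": 1},
  "[M+NH4]1+": {"delta": {"N": 1, "H": 4}, "charge": 1},
  "[M+NH4]1+ 13C": {"delta": {"N": 1, "H": 4}, "charge": 1, "n_c13": 1},
  "[M+Na]1+": {"delta": {"Na": 1}, "charge": 1},
  "[M-H]1-": {"delta": {"H": -1}, "charge": -1}
}
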