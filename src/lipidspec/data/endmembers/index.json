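{
  "Chol": {"file": "chol.csv", "baseline": 0.0},
  "DOPC": {"file": "dopc.csv", "baseline": 0.0},
  "SM": {"file": "sm.csv", "baseline": 0.0},
  "water": {"file": "water.csv", "baseline": 0.0},
  "carbon_tape": {"file": "carbon_tape.csv", "baseline": 1.0},
  "sucrose": {"file": "sucrose.csv", "baseline": 0.0},
  "MbCD_Chol_complex": {"file": "mbcd_chol_complex.csv", "baseline": 0.0},
  "DOPE": {"file": "dope.csv", "baseline": 0.0},
  "S1P": {"file": "s1p.csv", "baseline": 0.0}
}
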