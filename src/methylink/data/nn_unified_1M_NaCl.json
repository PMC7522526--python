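{
  "name": "unified-watson-crick-nearest-neighbor",
  "version": "1998-unified",
  "salt_conc_molar": 1.0,
  "units": {"dH": "kcal/mol", "dS": "cal/(mol*K)", "dG37": "kcal/mol"},
  "stacks": {
    "AA": {"dH": -7.9, "dS": -22.2, "dG37": -1.00},
    "TT": {"dH": -7.9, "dS": -22.2, "dG37": -1.00},
    "AT": {"dH": -7.2, "dS": -20.4, "dG37": -0.88},
    "TA": {"dH": -7.2, "dS": -21.3, "dG37": -0.58},
    "CA": {"dH": -8.5, "dS": -22.7, "dG37": -1.45},
    "TG": {"dH": -8.5, "dS": -22.7, "dG37": -1.45},
    "GT": {"dH": -8.4, "dS": -22.4, "dG37": -1.44},
    "AC": {"dH": -8.4, "dS": -22.4, "dG37": -1.44},
    "CT": {"dH": -7.8, "dS": -21.0, "dG37": -1.28},
    "AG": {"dH": -7.8, "dS": -21.0, "dG37": -1.28},
    "GA": {"dH": -8.2, "dS": -22.2, "dG37": -1.30},
    "TC": {"dH": -8.2, "dS": -22.2, "dG37": -1.30},
    "CG": {"dH": -10.6, "dS": -27.2, "dG37": -2.17},
    "GC": {"dH": -9.8, "dS": -24.4, "dG37": -2.24},
    "GG": {"dH": -8.0, "dS": -19.9, "dG37": -1.84},
    "CC": {"dH": -8.0, "dS": -19.9, "dG37": -1.84}
  },
  "initiation": {
    "GC": {"dH": 0.1, "dS": -2.8, "dG37": 0.98},
    "AT": {"dH": 2.3, "dS": 4.1, "dG37": 1.03}
  },
  "symmetry_correction": {"dH": 0.0, "dS": -1.4, "dG37": 0.43}
}
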