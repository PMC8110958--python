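{
  "comment": "Nearest-neighbor free-energy parameters at 37C, kcal/mol. Stacking entries are keyed by the closing pair (5' base, 3' base) then the enclosed pair. Loop initiation tables are by loop size; sizes beyond the table are extrapolated with lxc*ln(n/n_max).",
  "units": "kcal/mol",
  "stack": {
    "AU": {"AU": -0.9, "CG": -2.2, "GC": -2.1, "GU": -0.6, "UA": -1.1, "UG": -1.4},
    "CG": {"AU": -2.1, "CG": -3.3, "GC": -2.4, "GU": -1.4, "UA": -2.1, "UG": -2.1},
    "GC": {"AU": -2.4, "CG": -3.4, "GC": -3.3, "GU": -1.5, "UA": -2.2, "UG": -2.5},
    "GU": {"AU": -1.3, "CG": -2.5, "GC": -2.1, "GU": -0.5, "UA": -1.4, "UG": 1.3},
    "UA": {"AU": -1.3, "CG": -2.4, "GC": -2.1, "GU": -1.0, "UA": -0.9, "UG": -1.3},
    "UG": {"AU": -1.0, "CG": -1.5, "GC": -1.4, "GU": 0.3, "UA": -0.6, "UG": -0.5}
  },
  "hairpin": {"3": 5.4, "4": 5.6, "5": 5.7, "6": 5.4, "7": 6.0, "8": 5.5, "9": 6.4},
  "bulge": {"1": 3.8, "2": 2.8, "3": 3.2, "4": 3.6, "5": 4.0, "6": 4.4},
  "internal": {"2": 1.6, "3": 1.6, "4": 1.1, "5": 2.0, "6": 2.0, "7": 2.1, "8": 2.3, "9": 2.4, "10": 2.5},
  "internal_asym": 0.6,
  "internal_asym_max": 3.0,
  "ml_closing": 3.4,
  "ml_branch": 0.4,
  "ml_unpaired": 0.0,
  "lxc": 1.079,
  "max_interior_loop": 30
}
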