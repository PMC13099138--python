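{
  "version": "1.0",
  "comment": "Heavy-atom class parameters for the self-contained interface energy terms. sigma is the pair-potential minimum distance contribution (A), eps the well depth (kcal/mol), radius the atomic radius used by the solvation Gaussian (A), dg_free the solvation free energy of the isolated atom (kcal/mol; negative = burial favorable), lambda_ the solvation correlation length (A), volume the occluding volume (A^3).",
  "classes": {
    "C_ali":      {"sigma": 4.05, "eps": 0.105, "radius": 2.0,  "dg_free": -0.60, "lambda_": 3.5, "volume": 23.7},
    "C_aro":      {"sigma": 3.95, "eps": 0.120, "radius": 1.95, "dg_free": -0.45, "lambda_": 3.5, "volume": 18.4},
    "C_carbonyl": {"sigma": 3.70, "eps": 0.110, "radius": 1.85, "dg_free":  0.20, "lambda_": 3.5, "volume": 14.7},
    "N_amide":    {"sigma": 3.50, "eps": 0.170, "radius": 1.75, "dg_free":  1.00, "lambda_": 3.5, "volume": 11.2},
    "N_charged":  {"sigma": 3.50, "eps": 0.170, "radius": 1.75, "dg_free":  1.60, "lambda_": 6.0, "volume": 11.2},
    "O_carbonyl": {"sigma": 3.40, "eps": 0.160, "radius": 1.70, "dg_free":  1.10, "lambda_": 3.5, "volume": 10.8},
    "O_hydroxyl": {"sigma": 3.40, "eps": 0.160, "radius": 1.70, "dg_free":  1.20, "lambda_": 3.5, "volume": 10.8},
    "O_charged":  {"sigma": 3.40, "eps": 0.180, "radius": 1.70, "dg_free":  1.80, "lambda_": 6.0, "volume": 10.8},
    "S":          {"sigma": 4.10, "eps": 0.300, "radius": 2.05, "dg_free": -0.25, "lambda_": 3.5, "volume": 17.0}
  },
  "charges": {
    "backbone": {"N": -0.35, "CA": 0.35, "C": 0.35, "O": -0.35},
    "sidechain": {
      "LYS": {"NZ": 1.0},
      "ARG": {"NH1": 0.5, "NH2": 0.5},
      "ASP": {"OD1": -0.5, "OD2": -0.5},
      "GLU": {"OE1": -0.5, "OE2": -0.5}
    }
  },
  "weights": {"lj_atr": 1.0, "lj_rep": 0.55, "solv": 1.0, "elec": 1.0, "hbond": 1.0}
}
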