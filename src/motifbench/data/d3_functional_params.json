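{
  "_comment": [
    "BJ-damping global parameters (s6, s8, a1, a2[bohr]) per exchange-",
    "correlation functional, following the published BJ-damped fits where",
    "one exists.  M062X is conventionally fit with zero damping (s8 = 0);",
    "the entry here keeps the BJ functional form with the C8 channel",
    "switched off.  All entries are overridable at the API and CLI level."
  ],
  "functionals": {
    "BLYP":   {"s6": 1.0,  "s8": 2.6996, "a1": 0.4298, "a2": 4.2359},
    "TPSS":   {"s6": 1.0,  "s8": 1.9435, "a1": 0.4535, "a2": 4.4752},
    "B97":    {"s6": 1.0,  "s8": 2.2609, "a1": 0.5545, "a2": 3.2297},
    "wB97X":  {"s6": 1.0,  "s8": 0.2641, "a1": 0.0000, "a2": 5.4959},
    "B3LYP":  {"s6": 1.0,  "s8": 1.9889, "a1": 0.3981, "a2": 4.4211},
    "M062X":  {"s6": 1.0,  "s8": 0.0,    "a1": 0.0000, "a2": 5.8793},
    "PW6B95": {"s6": 1.0,  "s8": 0.7257, "a1": 0.2076, "a2": 6.3750},
    "B2PLYP": {"s6": 0.64, "s8": 0.9147, "a1": 0.3065, "a2": 5.0570},
    "PWPB95": {"s6": 0.82, "s8": 0.2904, "a1": 0.0000, "a2": 7.3141}
  }
}
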