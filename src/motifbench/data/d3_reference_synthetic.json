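{
  "_comment": [
    "SYNTHETIC element reference tables for the CN-dependent pairwise",
    "dispersion model.  Free-atom C6 coefficients (atomic units) follow",
    "standard literature values; the coordination-number dependence and the",
    "<r4>/<r2> Q ratios are constructed to reproduce the qualitative trends",
    "of published D3 parameterizations (C6 shrinks with increasing",
    "coordination; BJ radii sqrt(C8/C6) of 2.5-4 bohr).  They are a",
    "self-consistent stand-in, not a transcription of the published tables;",
    "absolute dispersion energies computed with them are model-internal.",
    "Units: radii bohr, C6 hartree*bohr^6, Q dimensionless."
  ],
  "covalent_radii_bohr": {
    "H": 0.604,
    "C": 1.417,
    "N": 1.342,
    "O": 1.191,
    "F": 1.077,
    "P": 2.022,
    "S": 1.946,
    "Cl": 1.871
  },
  "reference_points": {
    "H": [[0.0, 6.5], [0.91, 3.09]],
    "C": [[0.0, 49.1], [0.99, 43.3], [2.0, 30.4], [3.0, 25.8], [3.98, 18.2]],
    "N": [[0.0, 25.3], [0.94, 19.5], [2.01, 15.6], [2.99, 12.8]],
    "O": [[0.0, 15.5], [0.99, 12.1], [1.99, 10.4]],
    "F": [[0.0, 9.5], [1.0, 7.1]],
    "P": [[0.0, 122.0], [3.0, 88.0]],
    "S": [[0.0, 134.0], [0.99, 96.0], [1.99, 75.0]],
    "Cl": [[0.0, 94.6], [0.97, 67.0]]
  },
  "r4r2": {
    "H": 2.3,
    "C": 5.0,
    "N": 4.1,
    "O": 3.5,
    "F": 2.9,
    "P": 10.0,
    "S": 9.0,
    "Cl": 8.2
  }
}
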