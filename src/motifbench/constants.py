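"""Physical constants and element tables shared across the package."""

#: 1 hartree in kcal/mol.
HARTREE_TO_KCAL = 627.509

#: 1 angstrom in bohr.
ANGSTROM_TO_BOHR = 1.8897259886

#: Covalent radii in angstrom (Cordero-style single-bond radii), used for
#: distance-based bond perception.  Restricted to elements that occur in the
#: ligand-fragment/residue motifs handled here.
COVALENT_RADII = {
    "H": 0.31,
    "B": 0.84,
    "C": 0.76,
    "N": 0.71,
    "O": 0.66,
    "F": 0.57,
    "P": 1.07,
    "S": 1.05,
    "Cl": 1.02,
    "Br": 1.20,
    "I": 1.39,
}

#: Elements counted as "heavy" when measuring closest contact distances
#: between the two monomers of a motif (C, N, O only; S and halogens are
#: deliberately excluded from this particular descriptor).
HEAVY_CONTACT_ELEMENTS = frozenset({"C", "N", "O"})
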