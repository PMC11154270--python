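import math

import numpy as np
import pytest

from motifbench import dispersion
from motifbench.motifs import Atom, Monomer, MotifRecord


@pytest.fixture(scope="session")
def refdata():
    return dispersion.load_reference_data()


@pytest.fixture(scope="session")
def b3lyp_params():
    return dispersion.load_functional_params("B3LYP")


def ideal_benzene(center=(0.0, 0.0, 0.0), with_h=True):
    """Regular hexagon of carbons (optionally with radial hydrogens)."""
    atoms = []
    cx, cy, cz = center
    for k in range(6):
        ang = k * math.pi / 3
        atoms.append(
            Atom("C", f"C{k + 1}",
                 (cx + 1.395 * math.cos(ang), cy + 1.395 * math.sin(ang), cz))
        )
        if with_h:
            atoms.append(
                Atom("H", f"H{k + 1}",
                     (cx + 2.475 * math.cos(ang), cy + 2.475 * math.sin(ang), cz))
            )
    return atoms


@pytest.fixture
def benzene_monomer():
    return Monomer("ligand-fragment", "BNZ", ideal_benzene())


@pytest.fixture
def alanine_monomer():
    # alanine heavy atoms, roughly tetrahedral, no ring
    coords = {
        "N": (0.0, 0.0, 0.0),
        "CA": (1.46, 0.0, 0.0),
        "C": (2.0, 1.42, 0.0),
        "O": (1.3, 2.4, 0.0),
        "CB": (2.0, -0.75, 1.25),
    }
    atoms = [Atom(n[0], n, xyz, "B", "ALA", 7) for n, xyz in coords.items()]
    return Monomer("residue", "A7", atoms)


def two_atom_motif(el_a, el_b, distance, charge_a=0, charge_b=0):
    a = Monomer("ligand-fragment", "LIG", [Atom(el_a, el_a, (0.0, 0.0, 0.0))],
                formal_charge=charge_a)
    b = Monomer("residue", "X1", [Atom(el_b, el_b, (distance, 0.0, 0.0))],
                formal_charge=charge_b)
    return MotifRecord(monomers=(a, b))


def rigid_transform_atoms(atoms, rot, trans):
    return [
        Atom(a.element, a.name, tuple(rot @ np.asarray(a.coords) + trans),
             a.monomer_id, a.res_name, a.res_seq, a.occupancy, a.altloc)
        for a in atoms
    ]
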