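"""Interaction-energy assembly: supramolecular differences, counterpoise
bookkeeping, and the solvation thermodynamic cycle.

The gas-phase interaction energy of a dimer AB is the supramolecular
difference E_AB - E_A - E_B.  Basis-set superposition error is removed with
the Boys-Bernardi counterpoise scheme: each monomer is re-evaluated in the
full dimer basis by adding the partner's atoms as basis-only "ghost" centres,
and the corrected difference uses those ghost-augmented monomer energies.

Solution-phase energies follow a thermodynamic cycle: the gas-phase
interaction energy plus the dehydration energy

    dE_deh = G_sol(AB) - G_sol(A) - G_sol(B)

gives dE_aq = dE_gas + dE_deh.

External quantum-chemistry engines are never launched; a delimited "energy
ledger" (one electronic energy per motif/method/basis/fragment-role row) is
the interface.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .constants import HARTREE_TO_KCAL
from .motifs import Atom, MotifError, MotifRecord

__all__ = [
    "ROLES",
    "EnergyLedgerEntry",
    "CPFragmentSpec",
    "SolvationTriplet",
    "InteractionRecord",
    "supramolecular_delta",
    "counterpoise_fragments",
    "cp_corrected_delta",
    "dehydration",
    "aqueous",
    "read_ledger",
    "read_solvation",
    "assemble_records",
]

ROLES = ("dimer_AB", "monoA_ghostB", "monoB_ghostA", "monoA_alone", "monoB_alone")


@dataclass(frozen=True)
class EnergyLedgerEntry:
    motif_id: str
    method_label: str
    basis_label: str
    role: str
    energy: float  # hartree

    def __post_init__(self):
        if self.role not in ROLES:
            raise MotifError("unknown-role", self.role)


@dataclass
class CPFragmentSpec:
    role: str
    atoms: list[tuple[Atom, bool]]  # (atom, is_real)
    charge: int
    multiplicity: int = 1

    @property
    def n_real(self) -> int:
        return sum(1 for _, real in self.atoms if real)


@dataclass(frozen=True)
class SolvationTriplet:
    g_sol_ab: float  # kcal/mol
    g_sol_a: float
    g_sol_b: float


@dataclass(frozen=True)
class InteractionRecord:
    motif_id: str
    de_gas: float  # kcal/mol
    de_deh: float
    de_aq: float


def supramolecular_delta(e_ab: float, e_a: float, e_b: float) -> float:
    """Interaction energy as dimer minus monomers, in the input's units."""
    return e_ab - e_a - e_b


def counterpoise_fragments(motif: MotifRecord) -> list[CPFragmentSpec]:
    """The five fragment evaluations of a counterpoise-corrected dimer.

    Emits the real dimer, each monomer with the partner's atoms as ghost
    (basis-only) centres, and each isolated monomer.  Ghost fragments carry
    the real monomer's charge and multiplicity.
    """
    mono_a, mono_b = motif.monomers
    a_atoms = list(mono_a.atoms)
    b_atoms = list(mono_b.atoms)
    dimer_charge = mono_a.formal_charge + mono_b.formal_charge
    return [
        CPFragmentSpec(
            "dimer_AB",
            [(a, True) for a in a_atoms + b_atoms],
            dimer_charge,
            multiplicity=1,
        ),
        CPFragmentSpec(
            "monoA_ghostB",
            [(a, True) for a in a_atoms] + [(b, False) for b in b_atoms],
            mono_a.formal_charge,
            mono_a.multiplicity,
        ),
        CPFragmentSpec(
            "monoB_ghostA",
            [(a, False) for a in a_atoms] + [(b, True) for b in b_atoms],
            mono_b.formal_charge,
            mono_b.multiplicity,
        ),
        CPFragmentSpec("monoA_alone", [(a, True) for a in a_atoms],
                       mono_a.formal_charge, mono_a.multiplicity),
        CPFragmentSpec("monoB_alone", [(b, True) for b in b_atoms],
                       mono_b.formal_charge, mono_b.multiplicity),
    ]


def fragment_to_xyz(frag: CPFragmentSpec, comment: str = "") -> str:
    """XYZ-format fragment; ghost centres are marked with a ':' suffix."""
    lines = [str(len(frag.atoms)), comment or f"{frag.role} charge={frag.charge}"]
    for atom, real in frag.atoms:
        sym = atom.element if real else f"{atom.element}:"
        x, y, z = atom.coords
        lines.append(f"{sym:<4s} {x:12.6f} {y:12.6f} {z:12.6f}")
    return "\n".join(lines) + "\n"


def cp_corrected_delta(
    entries: Iterable[EnergyLedgerEntry] | Mapping[str, float],
) -> float:
    """Counterpoise-corrected interaction energy in kcal/mol.

    dE_CP = E(dimer) - E(monoA with ghost B) - E(monoB with ghost A),
    all evaluated in the dimer basis; input energies in hartree.
    """
    if isinstance(entries, Mapping):
        by_role = dict(entries)
    else:
        by_role = {e.role: e.energy for e in entries}
    missing = [r for r in ("dimer_AB", "monoA_ghostB", "monoB_ghostA") if r not in by_role]
    if missing:
        raise MotifError("incomplete-ledger", f"missing roles {missing}")
    delta_h = supramolecular_delta(
        by_role["dimer_AB"], by_role["monoA_ghostB"], by_role["monoB_ghostA"]
    )
    return delta_h * HARTREE_TO_KCAL


def dehydration(t: SolvationTriplet) -> float:
    """Dehydration energy of complex formation (kcal/mol)."""
    return t.g_sol_ab - t.g_sol_a - t.g_sol_b


def aqueous(de_gas: float, de_deh: float) -> float:
    """Solution-phase interaction energy via the thermodynamic cycle."""
    return de_gas + de_deh


LEDGER_COLUMNS = ["motif_id", "method_label", "basis_label", "role", "energy"]
SOLVATION_COLUMNS = ["motif_id", "g_sol_ab", "g_sol_a", "g_sol_b"]


def read_ledger(path) -> pd.DataFrame:
    """Read a delimited energy ledger; enforces schema and role uniqueness."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(LEDGER_COLUMNS) - set(df.columns)
    if missing:
        raise MotifError("incomplete-ledger", f"missing columns {sorted(missing)}")
    bad = set(df["role"]) - set(ROLES)
    if bad:
        raise MotifError("unknown-role", str(sorted(bad)))
    keys = df[["motif_id", "method_label", "basis_label", "role"]]
    if keys.duplicated().any():
        raise MotifError("incomplete-ledger", "duplicate ledger keys")
    return df


def read_solvation(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(SOLVATION_COLUMNS) - set(df.columns)
    if missing:
        raise MotifError("incomplete-ledger", f"missing columns {sorted(missing)}")
    return df


def assemble_records(
    ledger: pd.DataFrame,
    solvation: pd.DataFrame,
    method_label: str,
    basis_label: str,
) -> list[InteractionRecord]:
    """Build per-motif gas/dehydration/aqueous records for one method/basis.

    Gas-phase energies come from the counterpoise-corrected ledger roles;
    dehydration from the solvation triplets (kcal/mol)."""
    sub = ledger[
        (ledger["method_label"] == method_label)
        & (ledger["basis_label"] == basis_label)
    ]
    solv = solvation.set_index("motif_id")
    records = []
    for motif_id, grp in sub.groupby("motif_id", sort=True):
        by_role = dict(zip(grp["role"], grp["energy"]))
        de_gas = cp_corrected_delta(by_role)
        if motif_id not in solv.index:
            raise MotifError("incomplete-ledger", f"no solvation for {motif_id}")
        row = solv.loc[motif_id]
        de_deh = dehydration(
            SolvationTriplet(row["g_sol_ab"], row["g_sol_a"], row["g_sol_b"])
        )
        records.append(
            InteractionRecord(str(motif_id), de_gas, de_deh, aqueous(de_gas, de_deh))
        )
    return records
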