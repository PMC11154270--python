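"""Two-monomer interaction motifs: parsing, geometry, and mode classification.

A *motif* is a minimal two-body fragment cut out of a protein-ligand crystal
structure: the functional group of a small-molecule inhibitor (monomer A,
HETATM records) paired with a single interacting residue (monomer B, ATOM
records).  This module parses such fragments from PDB-format text, perceives
bonds and aromatic rings from geometry alone (the fragments carry no
connectivity), measures the descriptors used to characterise each interaction
(closest heavy-atom contact, ring-plane angle, hydrogen-bond angles and
donor-acceptor distances), and assigns one of five interaction modes:
CH-pi, pi-pi stacking, cation-pi, hydrogen bond, or salt bridge.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import gemmi
import networkx as nx
import numpy as np

from .constants import COVALENT_RADII, HEAVY_CONTACT_ELEMENTS

__all__ = [
    "Atom",
    "Monomer",
    "MotifRecord",
    "RingDescriptor",
    "GeometryReport",
    "MotifError",
    "parse_motif_pdb",
    "write_pdb",
    "perceive_bonds",
    "find_aromatic_rings",
    "closest_heavy_distance",
    "plane_angle",
    "hbond_geometry",
    "classify_mode",
]

# Classification envelopes.  Chosen to be inclusive of the geometries that
# occur in real kinase-inhibitor contacts of each mode; see docs/methods.md.
SALT_BRIDGE_MAX_DIST = 5.5  # angstrom, closest heavy contact of charged groups
CATION_PI_MAX_DIST = 6.0  # angstrom, ammonium N to ring centroid
HBOND_MAX_DA_DIST = 3.5  # angstrom, donor...acceptor
HBOND_MIN_DHA_ANGLE = 120.0  # degrees
PI_PI_MAX_CENTROID_DIST = 5.5  # angstrom, ring centroid to ring centroid
CH_PI_MAX_H_CENTROID = 3.5  # angstrom, aliphatic H to ring centroid
AROMATIC_PLANARITY_RMS = 0.1  # angstrom, max RMS deviation from LS plane
BOND_TOLERANCE = 1.3  # scale on the sum of covalent radii


class MotifError(ValueError):
    """Raised for contract violations; ``code`` is a short machine tag."""

    def __init__(self, code: str, message: str = ""):
        self.code = code
        super().__init__(f"{code}: {message}" if message else code)


@dataclass(frozen=True)
class Atom:
    element: str
    name: str
    coords: tuple[float, float, float]
    monomer_id: str = "A"
    res_name: str = "UNK"
    res_seq: int = 1
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self):
        if not all(math.isfinite(c) for c in self.coords):
            raise MotifError("non-finite-coords", f"atom {self.name}")

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.coords, dtype=float)


@dataclass
class Monomer:
    role: str  # "ligand-fragment" or "residue"
    label: str
    atoms: list[Atom]
    formal_charge: int = 0
    multiplicity: int = 1

    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)


@dataclass
class MotifRecord:
    monomers: tuple[Monomer, Monomer]
    motif_no: int | None = None
    mode: str | None = None
    pdb_id: str | None = None

    def __post_init__(self):
        if len(self.monomers) != 2:
            raise MotifError("two-monomers-required")

    def all_atoms(self) -> list[Atom]:
        return list(self.monomers[0].atoms) + list(self.monomers[1].atoms)


@dataclass
class RingDescriptor:
    member_atoms: tuple[int, ...]  # indices into the monomer's atom list
    centroid: np.ndarray
    unit_normal: np.ndarray
    planarity_rms: float


@dataclass
class GeometryReport:
    mode: str
    closest_heavy_distance: float
    plane_angle: float | None = None
    hbonds: list[tuple[float, float]] = field(default_factory=list)


# one-letter residue codes used for monomer labels like "A31" (Ala 31)
_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


def _resolve_altlocs(atoms: list[Atom]) -> list[Atom]:
    """Keep one copy per (res_seq, atom name): highest occupancy, ties -> 'A'."""
    groups: dict[tuple[int, str], list[Atom]] = {}
    order: list[tuple[int, str]] = []
    for a in atoms:
        key = (a.res_seq, a.name)
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(a)
    kept = []
    for key in order:
        cands = groups[key]
        if len(cands) == 1:
            kept.append(cands[0])
        else:
            # sort: highest occupancy first; among equals, altloc 'A' (and
            # blank before 'B') via plain lexicographic order
            cands = sorted(cands, key=lambda a: (-a.occupancy, a.altloc))
            kept.append(cands[0])
    return kept


def parse_motif_pdb(
    text: str,
    ligand_code: str,
    residue_seq: int,
    chain: str = "A",
    ligand_charge: int = 0,
    residue_charge: int = 0,
) -> MotifRecord:
    """Extract a two-monomer motif from PDB-format text.

    Monomer A is the ligand fragment (HETATM residue named ``ligand_code``
    on the given chain), monomer B the protein residue with sequence number
    ``residue_seq``.  Alternate locations are resolved to a single copy
    (highest occupancy, ties broken toward altloc 'A'); hydrogens are kept
    when present.
    """
    structure = gemmi.read_pdb_string(text)
    structure.setup_entities()
    lig_atoms: list[Atom] = []
    res_atoms: list[Atom] = []
    res_label = None
    if len(structure) == 0:
        raise MotifError("monomer-not-found", "no models in input")
    model = structure[0]
    for ch in model:
        if ch.name.strip() != chain:
            continue
        for res in ch:
            target = None
            if res.name.strip() == ligand_code:
                target = lig_atoms
            elif res.seqid.num == residue_seq:
                target = res_atoms
                one = _THREE_TO_ONE.get(res.name.strip(), res.name.strip())
                res_label = f"{one}{res.seqid.num}"
            if target is None:
                continue
            for at in res:
                target.append(
                    Atom(
                        element=at.element.name,
                        name=at.name,
                        coords=(at.pos.x, at.pos.y, at.pos.z),
                        monomer_id="A" if target is lig_atoms else "B",
                        res_name=res.name.strip(),
                        res_seq=res.seqid.num,
                        occupancy=at.occ,
                        altloc=at.altloc.strip() if at.altloc else "",
                    )
                )
    if not lig_atoms:
        raise MotifError("monomer-not-found", f"ligand {ligand_code} on chain {chain}")
    if not res_atoms:
        raise MotifError("monomer-not-found", f"residue {residue_seq} on chain {chain}")
    lig_atoms = _resolve_altlocs(lig_atoms)
    res_atoms = _resolve_altlocs(res_atoms)
    if not lig_atoms or not res_atoms:
        raise MotifError("empty-monomer")
    mono_a = Monomer("ligand-fragment", ligand_code, lig_atoms, ligand_charge)
    mono_b = Monomer("residue", res_label or f"X{residue_seq}", res_atoms, residue_charge)
    return MotifRecord(monomers=(mono_a, mono_b))


def write_pdb(motif: MotifRecord) -> str:
    """Serialize a motif as PDB text (monomer A as HETATM, B as ATOM)."""
    lines = []
    serial = 1
    for mono in motif.monomers:
        rectype = "HETATM" if mono.role == "ligand-fragment" else "ATOM"
        for a in mono.atoms:
            x, y, z = a.coords
            name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
            lines.append(
                f"{rectype:<6s}{serial:>5d} {name[:4]}{a.altloc or ' ':1s}"
                f"{a.res_name:>3s} A{a.res_seq:>4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{a.occupancy:6.2f}{0.0:6.2f}"
                f"          {a.element:>2s}"
            )
        lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


def perceive_bonds(atoms: Sequence[Atom]) -> list[tuple[int, int]]:
    """Distance-based bond perception.

    Two atoms are bonded iff their separation is at most 1.3 times the sum
    of their covalent radii.  Returns index pairs (i < j).
    """
    if len(atoms) == 0:
        raise MotifError("empty-monomer", "no atoms to bond")
    radii = []
    for a in atoms:
        r = COVALENT_RADII.get(a.element)
        if r is None:
            raise MotifError("unknown-element", a.element)
        radii.append(r)
    coords = np.array([a.coords for a in atoms])
    bonds = []
    for i in range(len(atoms)):
        d = np.linalg.norm(coords[i + 1:] - coords[i], axis=1)
        cut = BOND_TOLERANCE * (np.asarray(radii[i + 1:]) + radii[i])
        for off in np.nonzero(d <= cut)[0]:
            bonds.append((i, i + 1 + int(off)))
    return bonds


def _ring_descriptor(coords: np.ndarray, members: tuple[int, ...]) -> RingDescriptor:
    pts = coords[list(members)]
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    # plane normal = singular direction of the centered coordinates
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    normal = vt[-1]
    rms = float(s[-1] / math.sqrt(len(members)))
    return RingDescriptor(
        member_atoms=members,
        centroid=centroid,
        unit_normal=normal / np.linalg.norm(normal),
        planarity_rms=rms,
    )


def find_aromatic_rings(mono: Monomer) -> list[RingDescriptor]:
    """Detect planar 5- and 6-membered rings from the perceived bond graph.

    With no bond orders available, planarity is the aromaticity proxy: a
    cycle qualifies if its atoms fit a least-squares plane with RMS
    deviation at most 0.1 angstrom.  Hydrogens are excluded from cycles.
    """
    heavy_idx = [i for i, a in enumerate(mono.atoms) if a.element != "H"]
    if len(heavy_idx) < 5:
        return []
    heavy = [mono.atoms[i] for i in heavy_idx]
    bonds = perceive_bonds(heavy)
    g = nx.Graph(bonds)
    g.add_nodes_from(range(len(heavy)))
    coords = np.array([a.coords for a in mono.atoms])
    rings = []
    for cycle in nx.minimum_cycle_basis(g):
        if len(cycle) not in (5, 6):
            continue
        members = tuple(sorted(heavy_idx[i] for i in cycle))
        desc = _ring_descriptor(coords, members)
        if desc.planarity_rms <= AROMATIC_PLANARITY_RMS:
            rings.append(desc)
    rings.sort(key=lambda r: r.member_atoms)
    return rings


def closest_heavy_distance(motif: MotifRecord) -> float:
    """Minimum cross-monomer distance over C, N, and O atoms only."""
    coords = []
    for mono in motif.monomers:
        pts = np.array(
            [a.coords for a in mono.atoms if a.element in HEAVY_CONTACT_ELEMENTS]
        )
        if pts.size == 0:
            raise MotifError("no-heavy-atoms", f"monomer {mono.label}")
        coords.append(pts)
    diff = coords[0][:, None, :] - coords[1][None, :, :]
    return float(np.sqrt((diff**2).sum(axis=2)).min())


def plane_angle(ring_a: RingDescriptor, ring_b: RingDescriptor) -> float:
    """Angle between two ring planes in degrees, folded to [0, 90]."""
    dot = abs(float(np.dot(ring_a.unit_normal, ring_b.unit_normal)))
    return math.degrees(math.acos(min(1.0, dot)))


def _angle_deg(p1: np.ndarray, vertex: np.ndarray, p2: np.ndarray) -> float:
    v1 = p1 - vertex
    v2 = p2 - vertex
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return math.degrees(math.acos(max(-1.0, min(1.0, cosang))))


def hbond_geometry(motif: MotifRecord) -> list[tuple[float, float]]:
    """Cross-monomer hydrogen bonds as (D-H...A angle, D...A distance) pairs.

    Donors are N/O/S atoms bearing a covalently bound hydrogen, acceptors
    are N/O atoms of the other monomer.  A contact qualifies when the
    donor-acceptor distance is at most 3.5 angstrom and the D-H...A angle at
    least 120 degrees.  Sorted by descending angle.
    """
    if not any(a.element == "H" for a in motif.all_atoms()):
        raise MotifError("hydrogens-required")
    out = []
    for mono_d, mono_a in (motif.monomers, motif.monomers[::-1]):
        bonds = perceive_bonds(mono_d.atoms)
        adj: dict[int, list[int]] = {}
        for i, j in bonds:
            adj.setdefault(i, []).append(j)
            adj.setdefault(j, []).append(i)
        for di, datom in enumerate(mono_d.atoms):
            if datom.element not in ("N", "O", "S"):
                continue
            hydrogens = [
                h for h in adj.get(di, []) if mono_d.atoms[h].element == "H"
            ]
            for hi in hydrogens:
                hpos = mono_d.atoms[hi].xyz
                for aatom in mono_a.atoms:
                    if aatom.element not in ("N", "O"):
                        continue
                    da = float(np.linalg.norm(datom.xyz - aatom.xyz))
                    if da > HBOND_MAX_DA_DIST:
                        continue
                    ang = _angle_deg(datom.xyz, hpos, aatom.xyz)
                    if ang >= HBOND_MIN_DHA_ANGLE:
                        out.append((ang, da))
    out.sort(key=lambda t: -t[0])
    return out


def _has_hydrogens(motif: MotifRecord) -> bool:
    return any(a.element == "H" for a in motif.all_atoms())


def classify_mode(motif: MotifRecord) -> str:
    """Assign the interaction mode by a first-match decision cascade.

    Order: salt bridge, cation-pi, hydrogen bond, pi-pi stacking, CH-pi.
    Charged interactions are checked first because they dominate whenever
    their geometric signature is present.  Returns "unclassified" when no
    rule fires.
    """
    charges = [m.formal_charge for m in motif.monomers]
    rings = [find_aromatic_rings(m) for m in motif.monomers]

    # 1. salt bridge: opposite unit charges in close heavy-atom contact
    if sorted(charges) == [-1, 1]:
        try:
            if closest_heavy_distance(motif) <= SALT_BRIDGE_MAX_DIST:
                return "salt-bridge"
        except MotifError:
            pass

    # 2. cation-pi: a +1 monomer's nitrogen near the other monomer's ring
    for k in (0, 1):
        if motif.monomers[k].formal_charge == +1 and rings[1 - k]:
            n_atoms = [a for a in motif.monomers[k].atoms if a.element == "N"]
            for ring in rings[1 - k]:
                for n in n_atoms:
                    if np.linalg.norm(n.xyz - ring.centroid) <= CATION_PI_MAX_DIST:
                        return "cation-pi"

    # 3. hydrogen bond: at least one qualifying D-H...A triple
    if _has_hydrogens(motif):
        try:
            if hbond_geometry(motif):
                return "H-bond"
        except MotifError:
            pass

    # 4. pi-pi stacking: rings on both monomers with close centroids
    if rings[0] and rings[1]:
        for ra in rings[0]:
            for rb in rings[1]:
                if np.linalg.norm(ra.centroid - rb.centroid) <= PI_PI_MAX_CENTROID_DIST:
                    return "pi-pi"

    # 5. CH-pi: an aliphatic C-H pointing at the other monomer's ring
    for k in (0, 1):
        if not rings[1 - k]:
            continue
        mono = motif.monomers[k]
        ring_members = {i for r in rings[k] for i in r.member_atoms}
        bonds = perceive_bonds(mono.atoms)
        for i, j in bonds:
            for ci, hi in ((i, j), (j, i)):
                if mono.atoms[ci].element != "C" or mono.atoms[hi].element != "H":
                    continue
                if ci in ring_members:
                    continue  # aromatic C-H does not count as aliphatic
                hpos = mono.atoms[hi].xyz
                for ring in rings[1 - k]:
                    if np.linalg.norm(hpos - ring.centroid) <= CH_PI_MAX_H_CENTROID:
                        return "CH-pi"

    return "unclassified"


def measure(motif: MotifRecord) -> GeometryReport:
    """Classify a motif and compute its mode-appropriate descriptors."""
    mode = classify_mode(motif)
    dist = closest_heavy_distance(motif)
    report = GeometryReport(mode=mode, closest_heavy_distance=dist)
    if mode == "pi-pi":
        rings = [find_aromatic_rings(m) for m in motif.monomers]
        best = None
        for ra in rings[0]:
            for rb in rings[1]:
                sep = np.linalg.norm(ra.centroid - rb.centroid)
                if best is None or sep < best[0]:
                    best = (sep, ra, rb)
        if best is not None:
            report.plane_angle = plane_angle(best[1], best[2])
    elif mode == "H-bond":
        report.hbonds = hbond_geometry(motif)
    return report
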