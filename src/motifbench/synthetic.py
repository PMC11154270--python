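"""Synthetic input generators with exact ground truth.

Every input the pipeline consumes can be manufactured here with its true
value known by construction: ideal two-ring stacks at a requested plane
angle, dual hydrogen-bond pairs at requested angles/distances, charged
ion pairs, X^-3-convergent correlation-energy series, and counterpoise
energy ledgers whose per-method bias and noise are chosen up front.  The
generators exist so that every measurement routine can be tested against
a constructed truth rather than against itself.

All randomness flows through a single integer seed via numpy Generators;
fixed seed means bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cbs import CorrelationSeries
from .constants import HARTREE_TO_KCAL
from .motifs import Atom, Monomer, MotifError, MotifRecord, write_pdb

__all__ = [
    "FixtureSpec",
    "LedgerSpec",
    "LedgerBundle",
    "gen_ring_pair",
    "gen_hbond_pair",
    "gen_charged_pair",
    "gen_chpi_pair",
    "gen_fused_rings",
    "gen_random_cluster",
    "gen_cbs_series",
    "gen_ledger",
]

CC_AROMATIC = 1.395  # angstrom
CH_AROMATIC = 1.08
NH_BOND = 1.01
CH_BOND = 1.09


def _rotation_x(angle_deg: float) -> np.ndarray:
    a = math.radians(angle_deg)
    c, s = math.cos(a), math.sin(a)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])


def random_rigid_motion(rng: np.random.Generator):
    """A uniformly random rotation matrix and a translation vector."""
    # QR of a Gaussian matrix gives a Haar-random orthogonal matrix
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    t = rng.uniform(-10, 10, size=3)
    return q, t


def _apply_rigid(motif: MotifRecord, rot: np.ndarray, trans: np.ndarray) -> MotifRecord:
    new_monos = []
    for mono in motif.monomers:
        atoms = [
            Atom(a.element, a.name, tuple(rot @ a.xyz + trans), a.monomer_id,
                 a.res_name, a.res_seq, a.occupancy, a.altloc)
            for a in mono.atoms
        ]
        new_monos.append(Monomer(mono.role, mono.label, atoms,
                                 mono.formal_charge, mono.multiplicity))
    return MotifRecord(monomers=(new_monos[0], new_monos[1]),
                       motif_no=motif.motif_no, mode=motif.mode, pdb_id=motif.pdb_id)


@dataclass
class FixtureSpec:
    mode: str
    params: dict
    seed: int
    truth: dict


@dataclass
class LedgerSpec:
    """Recipe for a synthetic counterpoise ledger with known error structure."""

    n_motifs: int = 49
    mode_mix: dict[str, int] = field(default_factory=lambda: {
        "CH-pi": 13, "pi-pi": 12, "cation-pi": 8, "H-bond": 8, "salt-bridge": 8,
    })
    # per-mode (mean, sd) of the reference gas-phase interaction energy and of
    # the dehydration energy, kcal/mol; defaults sit at the scales observed
    # for real kinase-inhibitor motifs of each mode
    gas_scale: dict[str, tuple[float, float]] = field(default_factory=lambda: {
        "CH-pi": (-2.1, 0.8), "pi-pi": (-1.8, 1.0), "cation-pi": (-4.5, 2.9),
        "H-bond": (-5.5, 1.1), "salt-bridge": (-99.5, 14.5),
    })
    deh_scale: dict[str, tuple[float, float]] = field(default_factory=lambda: {
        "CH-pi": (0.4, 0.5), "pi-pi": (0.5, 0.4), "cation-pi": (2.9, 2.8),
        "H-bond": (3.6, 1.5), "salt-bridge": (100.1, 13.0),
    })
    # method label -> (bias b, noise sd sigma), kcal/mol
    methods: dict[str, tuple[float, float]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if any(sd < 0 for _, sd in self.methods.values()):
            raise MotifError("invalid-ledger-spec", "sigma must be >= 0")


@dataclass
class LedgerBundle:
    ledger: pd.DataFrame  # energy_assembly ledger schema, hartree
    solvation: pd.DataFrame  # solvation triplet schema, kcal/mol
    truth: pd.DataFrame  # motif_id, mode, ref dE_gas, dE_deh + per-method calc


def _benzene(
    center: np.ndarray,
    rot: np.ndarray,
    phase: float,
    names: list[str],
    h_names: list[str],
    res_name: str,
    res_seq: int,
    monomer_id: str,
) -> list[Atom]:
    """Ideal benzene (C6H6) with in-plane phase rotation, then rotated by
    ``rot`` and translated to ``center``.  Plane normal = rot @ z."""
    atoms = []
    for k in range(6):
        ang = phase + k * math.pi / 3
        for r, nm, el in (
            (CC_AROMATIC, names[k], "C"),
            (CC_AROMATIC + CH_AROMATIC, h_names[k], "H"),
        ):
            p = rot @ np.array([r * math.cos(ang), r * math.sin(ang), 0.0]) + center
            atoms.append(Atom(el, nm, tuple(p), monomer_id, res_name, res_seq))
    return atoms


_LIG_C = [f"C{i}" for i in range(1, 7)]
_LIG_H = [f"H{i}" for i in range(1, 7)]
_PHE_C = ["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]
_PHE_H = ["HG", "HD1", "HE1", "HZ", "HE2", "HD2"]


def gen_ring_pair(
    angle: float,
    centroid_sep: float,
    displacement: float = 0.0,
    seed: int = 0,
) -> tuple[str, dict]:
    """Two ideal six-membered rings at a requested plane angle and centroid
    separation.  Returns (PDB text, truth dict).

    Ring A lies in the z = 0 plane; ring B is tilted about x by ``angle``
    degrees with its centroid ``centroid_sep`` away (``displacement`` of
    that offset lies in-plane along x).
    """
    if not 0.0 <= angle <= 90.0:
        raise MotifError("infeasible-geometry", "angle must be in [0, 90]")
    if abs(displacement) >= centroid_sep:
        raise MotifError("infeasible-geometry", "displacement exceeds separation")
    rng = np.random.default_rng(seed)
    h = math.sqrt(centroid_sep**2 - displacement**2)
    center_b = np.array([displacement, 0.0, h])
    ring_a = _benzene(np.zeros(3), np.eye(3), rng.uniform(0, 2 * math.pi),
                      _LIG_C, _LIG_H, "LIG", 1, "A")
    ring_b = _benzene(center_b, _rotation_x(angle), rng.uniform(0, 2 * math.pi),
                      _PHE_C, _PHE_H, "PHE", 90, "B")
    motif = MotifRecord(monomers=(
        Monomer("ligand-fragment", "LIG", ring_a),
        Monomer("residue", "F90", ring_b),
    ))
    truth = {
        "mode": "pi-pi",
        "plane_angle": angle,
        "centroid_sep": centroid_sep,
    }
    return write_pdb(motif), truth


def _place_acceptor(
    donor: np.ndarray, hydrogen: np.ndarray, dha_angle: float, da_dist: float
) -> np.ndarray:
    """Acceptor position realizing a D-H...A angle and D...A distance, in the
    plane spanned by the D-H axis and +y."""
    hx = float(np.linalg.norm(hydrogen - donor))
    theta = math.radians(180.0 - dha_angle)  # from +x, measured at H
    # solve |donor -> acceptor| = da_dist with acceptor = H + r*(cos t, sin t, 0)
    disc = hx**2 * math.cos(theta) ** 2 - hx**2 + da_dist**2
    if disc < 0:
        raise MotifError("infeasible-geometry", "no acceptor position exists")
    r = -hx * math.cos(theta) + math.sqrt(disc)
    if r <= 0:
        raise MotifError("infeasible-geometry", "acceptor collapses onto donor")
    u = np.array([math.cos(theta), math.sin(theta), 0.0])
    return hydrogen + r * u


def gen_hbond_pair(
    angles: tuple[float, ...] | float,
    distances: tuple[float, ...] | float,
    seed: int = 0,
) -> tuple[str, dict]:
    """One or two donor-H...acceptor triples at requested geometry.

    The first bond donates ligand -> residue (N-H...O), the second residue ->
    ligand, mimicking the dual hinge-region hydrogen bonding of kinase
    inhibitors.  The two bonds are separated far enough that no unintended
    cross-contact satisfies the hydrogen-bond criteria.
    """
    if np.isscalar(angles):
        angles = (float(angles),)
    if np.isscalar(distances):
        distances = (float(distances),)
    if len(angles) != len(distances) or len(angles) not in (1, 2):
        raise MotifError("infeasible-geometry", "need one or two (angle, distance) pairs")
    for a, d in zip(angles, distances):
        if not (90.0 <= a <= 180.0) or not (2.5 <= d <= 3.5):
            raise MotifError("infeasible-geometry", f"angle {a} / distance {d} out of range")

    lig_atoms = []
    res_atoms = []
    # bond 1: ligand N1-H1 ... residue O
    n1 = np.zeros(3)
    h1 = np.array([NH_BOND, 0.0, 0.0])
    acc1 = _place_acceptor(n1, h1, angles[0], distances[0])
    lig_atoms += [Atom("N", "N1", tuple(n1), "A", "LIG", 1),
                  Atom("H", "HN1", tuple(h1), "A", "LIG", 1)]
    res_atoms += [Atom("O", "O", tuple(acc1), "B", "GLY", 83)]
    if len(angles) == 2:
        # bond 2: residue N-H ... ligand O1, shifted 4.2 A along z so neither
        # donor sees the other bond's acceptor within the 3.5 A cutoff
        dz = np.array([0.0, 0.0, 4.2])
        n2 = dz.copy()
        h2 = dz + np.array([NH_BOND, 0.0, 0.0])
        acc2 = _place_acceptor(n2, h2, angles[1], distances[1])
        res_atoms += [Atom("N", "N", tuple(n2), "B", "GLY", 83),
                      Atom("H", "H", tuple(h2), "B", "GLY", 83)]
        lig_atoms += [Atom("O", "O1", tuple(acc2), "A", "LIG", 1)]
    motif = MotifRecord(monomers=(
        Monomer("ligand-fragment", "LIG", lig_atoms),
        Monomer("residue", "G83", res_atoms),
    ))
    truth = {
        "mode": "H-bond",
        "hbonds": sorted(zip(angles, distances), key=lambda t: -t[0]),
    }
    return write_pdb(motif), truth


def _ammonium(origin: np.ndarray, axis: np.ndarray, res: tuple[str, int],
              monomer_id: str, names=("NZ", "HZ1", "HZ2", "HZ3", "CE")) -> list[Atom]:
    """Tetrahedral ammonium-like group: N at origin, three H around the -axis
    side, one C continuing along +axis."""
    axis = axis / np.linalg.norm(axis)
    # orthonormal frame
    ref = np.array([1.0, 0.0, 0.0]) if abs(axis[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(axis, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    res_name, res_seq = res
    atoms = [Atom("N", names[0], tuple(origin), monomer_id, res_name, res_seq)]
    for k in range(3):
        ang = 2 * math.pi * k / 3
        d = (-axis * math.cos(math.radians(70.5))
             + (e1 * math.cos(ang) + e2 * math.sin(ang)) * math.sin(math.radians(70.5)))
        atoms.append(Atom("H", names[1 + k], tuple(origin + NH_BOND * d),
                          monomer_id, res_name, res_seq))
    atoms.append(Atom("C", names[4], tuple(origin + 1.49 * axis),
                      monomer_id, res_name, res_seq))
    return atoms


def gen_charged_pair(
    mode: str, distance: float, seed: int = 0
) -> tuple[MotifRecord, dict]:
    """Ammonium/carboxylate (salt bridge) or benzene/ammonium (cation-pi)
    pair whose closest C/N/O contact equals ``distance``.

    The whole motif is given a random rigid rotation + translation (seeded),
    which leaves every descriptor invariant by construction.
    """
    rng = np.random.default_rng(seed)
    if mode == "salt-bridge":
        # ligand: methylammonium (+1); residue: carboxylate fragment (-1)
        lig = _ammonium(np.zeros(3), np.array([-1.0, 0.0, 0.0]), ("LIG", 1), "A",
                        names=("N1", "H11", "H12", "H13", "C1"))
        o1 = np.array([distance, 0.0, 0.0])
        cc = o1 + np.array([1.02, 0.72, 0.0])
        o2 = cc + np.array([1.02, -0.72, 0.0])
        cm = cc + np.array([0.40, 1.47, 0.0])
        res = [
            Atom("O", "OD1", tuple(o1), "B", "ASP", 148),
            Atom("C", "CG", tuple(cc), "B", "ASP", 148),
            Atom("O", "OD2", tuple(o2), "B", "ASP", 148),
            Atom("C", "CB", tuple(cm), "B", "ASP", 148),
        ]
        motif = MotifRecord(monomers=(
            Monomer("ligand-fragment", "LIG", lig, formal_charge=+1),
            Monomer("residue", "D148", res, formal_charge=-1),
        ))
        expected = "salt-bridge" if distance <= 5.5 else "unclassified"
    elif mode == "cation-pi":
        # ligand: benzene (neutral); residue: lysine-like ammonium (+1) on the
        # ring axis.  closest heavy contact = sqrt(h^2 + r_ring^2) = distance.
        if distance <= CC_AROMATIC:
            raise MotifError("infeasible-geometry", "distance below ring radius")
        h = math.sqrt(distance**2 - CC_AROMATIC**2)
        ring = _benzene(np.zeros(3), np.eye(3), rng.uniform(0, 2 * math.pi),
                        _LIG_C, _LIG_H, "LIG", 1, "A")
        amm = _ammonium(np.array([0.0, 0.0, h]), np.array([0.0, 0.0, 1.0]),
                        ("LYS", 33), "B")
        motif = MotifRecord(monomers=(
            Monomer("ligand-fragment", "LIG", ring, formal_charge=0),
            Monomer("residue", "K33", amm, formal_charge=+1),
        ))
        expected = "cation-pi" if h <= 6.0 else "unclassified"
    else:
        raise MotifError("unknown-mode", mode)
    rot, trans = random_rigid_motion(rng)
    motif = _apply_rigid(motif, rot, trans)
    truth = {"mode": expected, "closest_heavy_distance": distance}
    return motif, truth


def gen_chpi_pair(h_centroid_dist: float, seed: int = 0) -> tuple[MotifRecord, dict]:
    """Benzene (ligand) below an alanine-like methyl whose C-H points at the
    ring centroid from ``h_centroid_dist`` angstrom away."""
    rng = np.random.default_rng(seed)
    ring = _benzene(np.zeros(3), np.eye(3), rng.uniform(0, 2 * math.pi),
                    _LIG_C, _LIG_H, "LIG", 1, "A")
    h = np.array([0.0, 0.0, h_centroid_dist])
    cb = h + np.array([0.0, 0.0, CH_BOND])
    # two more methyl H's and the CA carbon, all pointing away from the ring
    hb2 = cb + CH_BOND * np.array([0.94, 0.0, 0.33])
    hb3 = cb + CH_BOND * np.array([-0.47, 0.82, 0.33])
    ca = cb + 1.52 * np.array([-0.47, -0.82, 0.33])
    res = [
        Atom("C", "CB", tuple(cb), "B", "ALA", 70),
        Atom("H", "HB1", tuple(h), "B", "ALA", 70),
        Atom("H", "HB2", tuple(hb2), "B", "ALA", 70),
        Atom("H", "HB3", tuple(hb3), "B", "ALA", 70),
        Atom("C", "CA", tuple(ca), "B", "ALA", 70),
    ]
    motif = MotifRecord(monomers=(
        Monomer("ligand-fragment", "LIG", ring),
        Monomer("residue", "A70", res),
    ))
    rot, trans = random_rigid_motion(rng)
    motif = _apply_rigid(motif, rot, trans)
    expected = "CH-pi" if h_centroid_dist <= 3.5 else "unclassified"
    return motif, {"mode": expected, "h_centroid_dist": h_centroid_dist}


def gen_fused_rings() -> Monomer:
    """Planar fused 5+6 ring system (indole-like skeleton) sharing one edge."""
    hexagon = [
        np.array([CC_AROMATIC * math.cos(k * math.pi / 3 + math.pi / 6),
                  CC_AROMATIC * math.sin(k * math.pi / 3 + math.pi / 6), 0.0])
        for k in range(6)
    ]
    # shared edge: hexagon vertices 0 and 5 (adjacent); build a regular
    # pentagon with the same edge on the +x side
    p0, p1 = hexagon[0], hexagon[5]
    mid = (p0 + p1) / 2
    edge = np.linalg.norm(p1 - p0)
    r5 = edge / (2 * math.sin(math.pi / 5))  # circumradius
    apo = r5 * math.cos(math.pi / 5)
    out = np.array([1.0, 0.0, 0.0])
    center5 = mid + apo * out
    # remaining three pentagon vertices: continue stepping 72 degrees past p1
    # in the rotational direction that goes p0 -> p1
    ang0 = math.atan2(p0[1] - center5[1], p0[0] - center5[0])
    ang1 = math.atan2(p1[1] - center5[1], p1[0] - center5[0])
    delta = (ang1 - ang0 + math.pi) % (2 * math.pi) - math.pi  # signed 72 degrees
    pts5 = [center5 + r5 * np.array([math.cos(ang1 + delta * k),
                                     math.sin(ang1 + delta * k), 0.0])
            for k in (1, 2, 3)]
    atoms = []
    for i, p in enumerate(hexagon):
        atoms.append(Atom("C", f"C{i + 1}", tuple(p), "A", "IND", 1))
    elements = ["N", "C", "C"]  # pyrrole-like: one nitrogen
    for i, (p, el) in enumerate(zip(pts5, elements)):
        atoms.append(Atom(el, f"{el}{i + 7}", tuple(p), "A", "IND", 1))
    return Monomer("ligand-fragment", "IND", atoms)


_CLUSTER_ELEMENTS = ("C", "H", "N", "O")


def gen_random_cluster(
    n_atoms: int, seed: int = 0, box: float = 6.0, min_sep: float = 1.0
) -> list[Atom]:
    """Random C/H/N/O cluster with a minimum interatomic separation,
    for dispersion-energy oracles."""
    rng = np.random.default_rng(seed)
    coords: list[np.ndarray] = []
    while len(coords) < n_atoms:
        p = rng.uniform(0, box, size=3)
        if all(np.linalg.norm(p - q) >= min_sep for q in coords):
            coords.append(p)
    elements = rng.choice(_CLUSTER_ELEMENTS, size=n_atoms)
    return [
        Atom(str(el), f"{el}{i + 1}", tuple(p), "A", "CLU", 1)
        for i, (el, p) in enumerate(zip(elements, coords))
    ]


def gen_cbs_series(e_inf: float, a: float, cardinals=(3, 4)) -> CorrelationSeries:
    """Correlation series following E(X) = E_inf + A * X^-3 exactly."""
    entries = [(int(x), e_inf + a * float(x) ** -3) for x in cardinals]
    return CorrelationSeries(entries=entries, label="cc-pVXZ")


# constant monomer energies used in ledger decomposition (hartree); only
# differences carry information, so their values are arbitrary
_E_MONO_A = -100.0
_E_MONO_B = -150.0
_G_SOL_A = -12.0
_G_SOL_B = -18.0


def gen_ledger(spec: LedgerSpec) -> LedgerBundle:
    """Counterpoise ledger + solvation triplets with known error structure.

    Per motif, a reference gas-phase interaction energy is drawn at the
    requested per-mode scale; each method's energy is reference + bias +
    Normal(0, sigma).  The interaction energy is placed entirely in the
    dimer entry (ghost energies equal isolated energies, i.e. zero BSSE),
    which is sufficient because only energy differences are observable.
    """
    rng = np.random.default_rng(spec.seed)
    modes = [m for m, k in spec.mode_mix.items() for _ in range(k)]
    if len(modes) < spec.n_motifs:
        # cycle the mix to reach the requested count
        reps = -(-spec.n_motifs // len(modes))
        modes = (modes * reps)[: spec.n_motifs]
    else:
        modes = modes[: spec.n_motifs]

    rows = []
    truth_rows = []
    solv_rows = []
    methods = {"reference": (0.0, 0.0), **spec.methods}
    for i, mode in enumerate(modes):
        motif_id = f"m{i + 1:04d}"
        mu, sd = spec.gas_scale[mode]
        ref = mu + sd * rng.standard_normal()
        dmu, dsd = spec.deh_scale[mode]
        deh = dmu + dsd * rng.standard_normal()
        truth = {"motif_id": motif_id, "mode": mode, "dE_gas": ref, "dE_deh": deh}
        for label, (bias, sigma) in methods.items():
            calc = ref if label == "reference" else (
                ref + bias + sigma * rng.standard_normal()
            )
            truth[f"calc_{label}"] = calc
            dimer = _E_MONO_A + _E_MONO_B + calc / HARTREE_TO_KCAL
            for role, energy in (
                ("dimer_AB", dimer),
                ("monoA_ghostB", _E_MONO_A),
                ("monoB_ghostA", _E_MONO_B),
                ("monoA_alone", _E_MONO_A),
                ("monoB_alone", _E_MONO_B),
            ):
                rows.append({
                    "motif_id": motif_id, "method_label": label,
                    "basis_label": "model", "role": role, "energy": energy,
                })
        solv_rows.append({
            "motif_id": motif_id,
            "g_sol_ab": _G_SOL_A + _G_SOL_B + deh,
            "g_sol_a": _G_SOL_A,
            "g_sol_b": _G_SOL_B,
        })
        truth_rows.append(truth)
    return LedgerBundle(
        ledger=pd.DataFrame(rows),
        solvation=pd.DataFrame(solv_rows),
        truth=pd.DataFrame(truth_rows),
    )
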