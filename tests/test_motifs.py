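"""Motif parsing, geometric descriptors, and mode classification."""

import math

import numpy as np
import pytest

from motifbench import motifs, synthetic
from motifbench.motifs import (
    Atom,
    Monomer,
    MotifError,
    MotifRecord,
    classify_mode,
    closest_heavy_distance,
    find_aromatic_rings,
    hbond_geometry,
    parse_motif_pdb,
    perceive_bonds,
    plane_angle,
    write_pdb,
)

from conftest import ideal_benzene, rigid_transform_atoms, two_atom_motif


class TestParsing:
    def test_ligand_and_residue_split_with_expected_atom_counts(self):
        txt, _ = synthetic.gen_ring_pair(0.0, 3.5)
        motif = parse_motif_pdb(txt, "LIG", 90)
        assert motif.monomers[0].role == "ligand-fragment"
        assert motif.monomers[0].label == "LIG"
        assert motif.monomers[1].label == "F90"
        assert len(motif.monomers[0].atoms) == 12  # C6H6
        assert len(motif.monomers[1].atoms) == 12

    def test_missing_ligand_raises(self):
        txt, _ = synthetic.gen_ring_pair(0.0, 3.5)
        with pytest.raises(MotifError, match="monomer-not-found"):
            parse_motif_pdb(txt, "XYZ", 90)
        with pytest.raises(MotifError, match="monomer-not-found"):
            parse_motif_pdb(txt, "LIG", 999)

    def test_altloc_resolved_to_highest_occupancy_then_A(self):
        base = (
            "HETATM    1  C1 ALIG A   1       0.000   0.000   0.000  0.40          C\n"
            "HETATM    2  C1 BLIG A   1       1.000   0.000   0.000  0.60          C\n"
            "HETATM    3  C2 ALIG A   1       2.000   0.000   0.000  0.50          C\n"
            "HETATM    4  C2 BLIG A   1       3.000   0.000   0.000  0.50          C\n"
            "ATOM      5  N   GLY A   9       5.000   0.000   0.000  1.00          N\n"
            "END\n"
        )
        motif = parse_motif_pdb(base, "LIG", 9)
        lig = motif.monomers[0]
        assert len(lig.atoms) == 2
        by_name = {a.name: a for a in lig.atoms}
        # C1: occupancy 0.60 wins (altloc B)
        assert by_name["C1"].coords[0] == pytest.approx(1.0)
        # C2: tie broken toward altloc A
        assert by_name["C2"].coords[0] == pytest.approx(2.0)

    def test_pdb_round_trip_preserves_coordinates(self):
        motif, _ = synthetic.gen_charged_pair("salt-bridge", 3.4, seed=11)
        txt = write_pdb(motif)
        back = parse_motif_pdb(txt, "LIG", 148)
        orig = np.vstack([m.coords() for m in motif.monomers])
        new = np.vstack([m.coords() for m in back.monomers])
        assert np.abs(orig - new).max() < 1e-3  # fixed-width PDB precision


class TestBondsAndRings:
    def test_bond_perception_distance_window(self):
        near = [Atom("C", "C1", (0, 0, 0)), Atom("C", "C2", (1.4, 0, 0))]
        far = [Atom("C", "C1", (0, 0, 0)), Atom("C", "C2", (3.0, 0, 0))]
        assert perceive_bonds(near) == [(0, 1)]
        assert perceive_bonds(far) == []

    def test_unknown_element_rejected(self):
        with pytest.raises(MotifError, match="unknown-element"):
            perceive_bonds([Atom("Xx", "X1", (0, 0, 0))])

    def test_benzene_has_exactly_six_ring_bonds(self):
        carbons = [a for a in ideal_benzene() if a.element == "C"]
        bonds = perceive_bonds(carbons)
        # oracle: brute-force distance scan at the aromatic C-C length
        expected = {
            (i, j)
            for i in range(6)
            for j in range(i + 1, 6)
            if np.linalg.norm(np.subtract(carbons[i].coords, carbons[j].coords)) < 1.5
        }
        assert set(bonds) == expected
        assert len(bonds) == 6

    def test_benzene_yields_one_planar_ring(self, benzene_monomer):
        rings = find_aromatic_rings(benzene_monomer)
        assert len(rings) == 1
        assert rings[0].planarity_rms == pytest.approx(0.0, abs=1e-8)
        assert np.linalg.norm(rings[0].unit_normal) == pytest.approx(1.0, abs=1e-10)

    def test_alanine_has_no_rings(self, alanine_monomer):
        assert find_aromatic_rings(alanine_monomer) == []

    def test_fused_five_six_system_gives_two_rings_sharing_an_edge(self):
        mono = synthetic.gen_fused_rings()
        rings = find_aromatic_rings(mono)
        assert sorted(len(r.member_atoms) for r in rings) == [5, 6]
        shared = set(rings[0].member_atoms) & set(rings[1].member_atoms)
        assert len(shared) == 2

    @pytest.mark.parametrize("n_rings", [1, 2, 3])
    def test_ring_count_matches_cycle_basis_oracle(self, n_rings):
        # n separate benzenes merged into one monomer
        atoms = []
        for k in range(n_rings):
            atoms.extend(ideal_benzene(center=(8.0 * k, 0, 0)))
        mono = Monomer("ligand-fragment", "LIG", atoms)
        rings = find_aromatic_rings(mono)
        import networkx as nx

        heavy = [a for a in atoms if a.element != "H"]
        g = nx.Graph(perceive_bonds(heavy))
        assert len(rings) == len(nx.minimum_cycle_basis(g)) == n_rings


class TestDistances:
    def test_single_pair(self):
        assert closest_heavy_distance(two_atom_motif("C", "C", 3.5)) == pytest.approx(3.5)

    def test_sulfur_excluded_from_heavy_contact(self):
        a = Monomer("ligand-fragment", "LIG",
                    [Atom("S", "S1", (0, 0, 0)), Atom("C", "C1", (0, 0, 3.0))])
        b = Monomer("residue", "X1",
                    [Atom("S", "S2", (3.0, 0, 0)), Atom("C", "C2", (3.4, 0, 3.0))])
        motif = MotifRecord(monomers=(a, b))
        # S-S pair at 3.0 is ignored; closest C-C pair is 3.4
        assert closest_heavy_distance(motif) == pytest.approx(3.4)

    def test_no_eligible_atoms_raises(self):
        with pytest.raises(MotifError, match="no-heavy-atoms"):
            closest_heavy_distance(two_atom_motif("S", "C", 3.0))

    def test_symmetric_under_monomer_swap_and_rigid_motion(self):
        motif, _ = synthetic.gen_charged_pair("salt-bridge", 4.0, seed=1)
        d = closest_heavy_distance(motif)
        swapped = MotifRecord(monomers=(motif.monomers[1], motif.monomers[0]))
        assert closest_heavy_distance(swapped) == pytest.approx(d, abs=1e-12)
        rng = np.random.default_rng(4)
        rot, trans = synthetic.random_rigid_motion(rng)
        moved = MotifRecord(monomers=tuple(
            Monomer(m.role, m.label, rigid_transform_atoms(m.atoms, rot, trans),
                    m.formal_charge) for m in motif.monomers))
        assert closest_heavy_distance(moved) == pytest.approx(d, abs=1e-8)


class TestPlaneAngle:
    def _rings(self, angle, sep=3.5):
        txt, _ = synthetic.gen_ring_pair(angle, sep)
        motif = parse_motif_pdb(txt, "LIG", 90)
        ra = find_aromatic_rings(motif.monomers[0])[0]
        rb = find_aromatic_rings(motif.monomers[1])[0]
        return ra, rb

    @pytest.mark.parametrize("angle", [0.0, 43.85, 90.0])
    def test_constructed_angle_recovered(self, angle):
        ra, rb = self._rings(angle)
        assert plane_angle(ra, rb) == pytest.approx(angle, abs=0.01)

    def test_symmetric_and_rigid_motion_invariant(self):
        ra, rb = self._rings(37.0, sep=4.0)
        assert plane_angle(ra, rb) == pytest.approx(plane_angle(rb, ra), abs=1e-10)
        rng = np.random.default_rng(9)
        rot, _ = synthetic.random_rigid_motion(rng)
        from motifbench.motifs import RingDescriptor

        def rotate(r):
            return RingDescriptor(r.member_atoms, rot @ r.centroid,
                                  rot @ r.unit_normal, r.planarity_rms)

        assert plane_angle(rotate(ra), rotate(rb)) == pytest.approx(
            plane_angle(ra, rb), abs=1e-8
        )


class TestHbondGeometry:
    def test_collinear_bond(self):
        txt, _ = synthetic.gen_hbond_pair(180.0, 2.90)
        motif = parse_motif_pdb(txt, "LIG", 83)
        (angle, dist), = hbond_geometry(motif)
        assert angle == pytest.approx(180.0, abs=0.1)
        assert dist == pytest.approx(2.90, abs=0.005)

    def test_dual_bond_recovered_sorted_by_angle(self):
        txt, _ = synthetic.gen_hbond_pair((158.59, 166.51), (2.88, 2.94))
        motif = parse_motif_pdb(txt, "LIG", 83)
        got = hbond_geometry(motif)
        assert len(got) == 2
        assert got[0][0] >= got[1][0]
        assert got[0][0] == pytest.approx(166.51, abs=0.05)
        assert got[0][1] == pytest.approx(2.94, abs=0.005)
        assert got[1][0] == pytest.approx(158.59, abs=0.05)
        assert got[1][1] == pytest.approx(2.88, abs=0.005)

    def test_no_donor_gives_empty_list(self):
        motif, _ = synthetic.gen_chpi_pair(3.0, seed=0)
        assert hbond_geometry(motif) == []

    def test_missing_hydrogens_raise(self):
        with pytest.raises(MotifError, match="hydrogens-required"):
            hbond_geometry(two_atom_motif("N", "O", 2.9))


class TestClassification:
    def test_salt_bridge_close_pair(self):
        motif, truth = synthetic.gen_charged_pair("salt-bridge", 3.4, seed=0)
        assert classify_mode(motif) == "salt-bridge" == truth["mode"]

    def test_neutral_perpendicular_rings_are_pi_pi(self):
        txt, _ = synthetic.gen_ring_pair(90.0, 5.0)
        assert classify_mode(parse_motif_pdb(txt, "LIG", 90)) == "pi-pi"

    def test_dual_hbond_fixture(self):
        txt, _ = synthetic.gen_hbond_pair((160.0, 150.0), (2.9, 3.0))
        assert classify_mode(parse_motif_pdb(txt, "LIG", 83)) == "H-bond"

    def test_out_of_envelope_salt_bridge_unclassified(self):
        motif, truth = synthetic.gen_charged_pair("salt-bridge", 9.0, seed=0)
        assert classify_mode(motif) == "unclassified" == truth["mode"]

    @pytest.mark.parametrize("mode", ["CH-pi", "pi-pi", "cation-pi", "H-bond",
                                      "salt-bridge"])
    def test_twenty_random_in_envelope_draws_classify_correctly(self, mode):
        rng = np.random.default_rng(20260201)
        for k in range(20):
            seed = int(rng.integers(0, 2**31))
            if mode == "pi-pi":
                angle = float(rng.uniform(0, 90))
                sep = float(rng.uniform(3.3, 5.4))
                txt, _ = synthetic.gen_ring_pair(angle, sep, seed=seed)
                motif = parse_motif_pdb(txt, "LIG", 90)
            elif mode == "H-bond":
                a = tuple(rng.uniform(135, 178, size=2))
                d = tuple(rng.uniform(2.7, 3.4, size=2))
                txt, _ = synthetic.gen_hbond_pair(a, d, seed=seed)
                motif = parse_motif_pdb(txt, "LIG", 83)
            elif mode == "CH-pi":
                motif, _ = synthetic.gen_chpi_pair(float(rng.uniform(2.3, 3.4)),
                                                   seed=seed)
            elif mode == "cation-pi":
                motif, _ = synthetic.gen_charged_pair(
                    "cation-pi", float(rng.uniform(3.0, 5.2)), seed=seed)
            else:
                motif, _ = synthetic.gen_charged_pair(
                    "salt-bridge", float(rng.uniform(2.9, 5.4)), seed=seed)
            assert classify_mode(motif) == mode, f"{mode} draw {k} misclassified"


class TestMeasure:
    def test_pi_pi_report_carries_plane_angle(self):
        txt, _ = synthetic.gen_ring_pair(43.85, 3.55)
        report = motifs.measure(parse_motif_pdb(txt, "LIG", 90))
        assert report.mode == "pi-pi"
        assert report.plane_angle == pytest.approx(43.85, abs=0.05)

    def test_hbond_report_carries_bond_list(self):
        txt, _ = synthetic.gen_hbond_pair((161.45,), (3.14,))
        report = motifs.measure(parse_motif_pdb(txt, "LIG", 83))
        assert report.mode == "H-bond"
        assert len(report.hbonds) == 1
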