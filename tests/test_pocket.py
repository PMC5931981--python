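"""Contact detection, metal coordination, ring orientation, distances."""

import copy

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from ppisig.model_io import Atom, Residue, StructureModel, ChainModel
from ppisig.pocket import (
    hbond_contacts,
    metal_shell,
    nearest_distance,
    pocket_residues,
    ring_orientation_diff,
)
from ppisig.synth import synth_ring_pair, synth_structure
from tests.conftest import random_rotation


def rigid_move(model, r, t):
    out = copy.deepcopy(model)
    for res in out.all_residues():
        for atom in res.atoms:
            atom.coords = atom.coords @ r.T + t
    return out


def brute_force_pocket(model, ligand, cutoff):
    lig = np.array([a.coords for a in ligand.heavy_atoms()])
    found = {}
    for chain in model.chains:
        for res in chain.amino_residues():
            xyz = np.array([a.coords for a in res.heavy_atoms()])
            d = cdist(xyz, lig).min()
            if d <= cutoff:
                found[res.key] = d
    return found


class TestPocketResidues:
    def test_planted_residue_recovered(self):
        model, truth = synth_structure(40, pocket_residue=20, pocket_distance=3.0, seed=1)
        lig = model.hetero_by_name("LIG")[0]
        hits = pocket_residues(model, lig, 4.0)
        assert [(r.number, pytest.approx(d, abs=1e-9)) for r, d in hits] == [(20, 3.0)]

    def test_matches_brute_force(self):
        model, _ = synth_structure(60, pocket_residue=30, pocket_distance=3.5, seed=2)
        lig = model.hetero_by_name("LIG")[0]
        for cutoff in (2.0, 4.0, 8.0, 25.0):
            hits = {r.key: d for r, d in pocket_residues(model, lig, cutoff)}
            oracle = brute_force_pocket(model, lig, cutoff)
            assert hits.keys() == oracle.keys()
            for k in hits:
                assert hits[k] == pytest.approx(oracle[k], abs=1e-9)

    def test_zero_cutoff_empty(self):
        model, _ = synth_structure(20, pocket_residue=10, pocket_distance=3.0, seed=3)
        assert pocket_residues(model, model.hetero_by_name("LIG")[0], 0.0) == []

    def test_monotone_in_cutoff(self):
        model, _ = synth_structure(50, pocket_residue=25, pocket_distance=2.5, seed=4)
        lig = model.hetero_by_name("LIG")[0]
        prev: set = set()
        for cutoff in (1.0, 3.0, 5.0, 10.0, 30.0):
            cur = {r.key for r, _ in pocket_residues(model, lig, cutoff)}
            assert prev <= cur
            prev = cur


def _two_atom_structure(res_atom, lig_atom, d):
    """One residue with one polar atom at distance d from a one-atom ligand."""
    res = Residue("A", 1, "", "ASN", kind="amino_acid")
    res.atoms.append(Atom(1, res_atom, res_atom[0], np.zeros(3)))
    lig = Residue("A", 90, "", "UNL", kind="ligand")
    lig.atoms.append(Atom(2, lig_atom, lig_atom[0], np.array([d, 0.0, 0.0])))
    model = StructureModel("toy", chains=[ChainModel("A", [res])], hetero=[lig])
    return model, lig


class TestHbondContacts:
    def test_polar_pair_within_range(self):
        model, lig = _two_atom_structure("ND2", "O1", 2.8)
        contacts = hbond_contacts(model, lig, 3.5)
        assert len(contacts) == 1
        assert contacts[0].contact_class == "hbond"
        assert not contacts[0].via_backbone

    def test_pair_beyond_cutoff(self):
        model, lig = _two_atom_structure("ND2", "O1", 4.0)
        assert hbond_contacts(model, lig, 3.5) == []

    def test_ionic_classification(self):
        # Arg guanidinium nitrogen vs an oxygen of a phosphate-bearing ligand
        res = Residue("A", 1, "", "ARG", kind="amino_acid")
        res.atoms.append(Atom(1, "NH1", "N", np.zeros(3)))
        lig = Residue("A", 90, "", "PCP", kind="ligand")
        lig.atoms.append(Atom(2, "O1", "O", np.array([2.9, 0.0, 0.0])))
        lig.atoms.append(Atom(3, "P1", "P", np.array([4.2, 0.0, 0.0])))
        model = StructureModel("toy", chains=[ChainModel("A", [res])], hetero=[lig])
        contacts = hbond_contacts(model, lig, 3.5)
        assert [c.contact_class for c in contacts] == ["ionic"]

    def test_contacts_within_pocket_at_same_cutoff(self):
        model, _ = synth_structure(40, pocket_residue=20, pocket_distance=3.0, seed=5)
        lig = model.hetero_by_name("LIG")[0]
        pocket_keys = {r.key for r, _ in pocket_residues(model, lig, 3.5)}
        for c in hbond_contacts(model, lig, 3.5):
            assert c.distance <= 3.5
            assert c.residue.key in pocket_keys


class TestMetalShell:
    def test_planted_octahedron(self):
        model, truth = synth_structure(20, plant_metal=True, n_waters=6, water_radius=2.1, seed=6)
        mg = [r for r in model.hetero if r.kind == "metal"][0]
        shell = metal_shell(model, mg, 2.8)
        assert shell.coordination_number == 6
        assert shell.octahedricity == pytest.approx(0.0, abs=1e-9)
        assert all(d == pytest.approx(2.1, abs=1e-9) for _, d, _ in shell.ligands)
        assert all(kind == "water" for _, _, kind in shell.ligands)

    def test_empty_shell(self):
        model, _ = synth_structure(20, plant_metal=True, n_waters=0, seed=7)
        mg = [r for r in model.hetero if r.kind == "metal"][0]
        assert metal_shell(model, mg, 2.8).coordination_number == 0

    def test_octahedricity_invariant_under_rigid_motion_and_order(self, rng):
        model, _ = synth_structure(20, plant_metal=True, n_waters=5, seed=8)
        mg = [r for r in model.hetero if r.kind == "metal"][0]
        base = metal_shell(model, mg, 2.8)
        moved = rigid_move(model, random_rotation(rng), rng.normal(size=3) * 10)
        mg2 = [r for r in moved.hetero if r.kind == "metal"][0]
        shell2 = metal_shell(moved, mg2, 2.8)
        assert shell2.octahedricity == pytest.approx(base.octahedricity, abs=1e-9)
        shuffled = copy.deepcopy(base)
        shuffled.ligands = shuffled.ligands[::-1]
        assert shuffled.octahedricity == pytest.approx(base.octahedricity, abs=1e-12)


class TestRingOrientation:
    def test_ring_vs_itself(self):
        a, _, _ = synth_ring_pair(0.0, 0.0, seed=1)
        ro = ring_orientation_diff(a, a)
        assert ro.tilt_deg == pytest.approx(0.0, abs=1e-9)
        assert ro.rotation_deg % 360.0 == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("tilt,rot", [(35.0, 120.0), (10.0, 0.0), (0.0, 250.0), (60.0, 300.0)])
    def test_planted_angles_recovered(self, tilt, rot):
        a, b, _ = synth_ring_pair(tilt, rot, seed=9)
        ro = ring_orientation_diff(a, b)
        assert ro.tilt_deg == pytest.approx(tilt, abs=1e-6)
        assert ro.rotation_deg % 360.0 == pytest.approx(rot % 360.0, abs=1e-6)

    def test_tilt_fold_boundary(self):
        a, b, _ = synth_ring_pair(90.0, 0.0, seed=10)
        assert ring_orientation_diff(a, b).tilt_deg == pytest.approx(90.0, abs=1e-6)

    def test_antisymmetry(self):
        a, b, _ = synth_ring_pair(25.0, 140.0, seed=11)
        fwd = ring_orientation_diff(a, b)
        rev = ring_orientation_diff(b, a)
        assert fwd.tilt_deg == pytest.approx(rev.tilt_deg, abs=1e-9)
        assert (fwd.rotation_deg + rev.rotation_deg) % 360.0 == pytest.approx(0.0, abs=1e-6)

    def test_missing_atom_rejected(self):
        a, b, _ = synth_ring_pair(20.0, 50.0, seed=12)
        with pytest.raises(ValueError, match="C6"):
            ring_orientation_diff(a[:5], b)

    def test_collinear_rejected(self):
        line = {f"C{i+1}": np.array([float(i), 0.0, 0.0]) for i in range(6)}
        a, _, _ = synth_ring_pair(0.0, 0.0, seed=13)
        with pytest.raises(ValueError, match="collinear"):
            ring_orientation_diff(line, a)


class TestNearestDistance:
    def test_two_atoms(self):
        a = [Atom(1, "O1", "O", np.zeros(3))]
        b = [Atom(2, "O2", "O", np.array([5.0, 0.0, 0.0]))]
        d, (pa, pb) = nearest_distance(a, b)
        assert d == pytest.approx(5.0)
        assert (pa.name, pb.name) == ("O1", "O2")

    def test_matches_double_loop(self, rng):
        ga = [Atom(i, f"A{i}", "C", rng.normal(size=3) * 8) for i in range(20)]
        gb = [Atom(i, f"B{i}", "O", rng.normal(size=3) * 8) for i in range(20)]
        d, _ = nearest_distance(ga, gb)
        oracle = min(
            np.linalg.norm(x.coords - y.coords) for x in ga for y in gb
        )
        assert d == pytest.approx(oracle, abs=1e-12)

    def test_empty_group_rejected(self):
        a = [Atom(1, "O1", "O", np.zeros(3))]
        with pytest.raises(ValueError):
            nearest_distance(a, [])

    def test_distances_rigid_invariant(self, rng):
        model, _ = synth_structure(30, pocket_residue=15, pocket_distance=3.2, seed=14)
        lig = model.hetero_by_name("LIG")[0]
        res = model.chains[0].residues[14]
        d0, _ = nearest_distance(res.atoms, lig.atoms)
        moved = rigid_move(model, random_rotation(rng), rng.normal(size=3) * 20)
        d1, _ = nearest_distance(
            moved.chains[0].residues[14].atoms, moved.hetero_by_name("LIG")[0].atoms
        )
        assert d1 == pytest.approx(d0, abs=1e-9)
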