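"""Rigid superposition, trimming, and structure-guided correspondence."""

import copy
import itertools

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from ppisig.superpose import (
    DegenerateCoordinatesError,
    PairCorrespondence,
    SuperpositionResult,
    correspondence_from_superposition,
    kabsch,
    structure_alignment,
    trimmed_superpose,
    _lis_pairs,
)
from ppisig.synth import perturb_structure, synth_structure
from tests.conftest import random_rotation

# fixed 4-point toy set for oracle comparison
TOY_A = np.array([[0.0, 0.0, 0.0], [1.5, 0.2, -0.3], [0.4, 2.1, 0.7], [-1.0, 0.8, 1.9]])
TOY_B = np.array([[0.3, -0.1, 0.2], [1.8, 0.9, 0.1], [-0.2, 2.0, 1.1], [-0.9, 0.2, 2.4]])


def grid_search_rmsd(a, b, coarse_deg=20.0):
    """Independent oracle: best RMSD over a rotation grid plus local polish.

    For any fixed rotation the optimal translation matches the centroids,
    so only the rotation is searched.
    """
    ac, bc = a - a.mean(0), b - b.mean(0)

    def rmsd_of(angles):
        r = Rotation.from_euler("zyx", angles, degrees=True).as_matrix()
        return float(np.sqrt(np.mean(np.sum((ac @ r.T - bc) ** 2, axis=1))))

    grid = np.arange(-180.0, 180.0, coarse_deg)
    best = min(
        (rmsd_of((z, y, x)), (z, y, x))
        for z, y, x in itertools.product(grid, np.arange(-90.0, 91.0, coarse_deg), grid)
    )
    res = minimize(rmsd_of, best[1], method="Nelder-Mead",
                   options={"xatol": 1e-8, "fatol": 1e-12, "maxiter": 5000})
    return float(res.fun)


class TestKabsch:
    def test_identical_sets(self, rng):
        a = rng.normal(size=(10, 3))
        s = kabsch(a, a)
        assert s.rmsd == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(s.rotation, np.eye(3), atol=1e-9)

    def test_recovers_known_rotation(self, rng):
        a = rng.normal(size=(25, 3)) * 4
        r = random_rotation(rng)
        t = np.array([2.0, -5.0, 1.5])
        s = kabsch(a, a @ r.T + t)
        assert s.rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(s.rotation, r, atol=1e-6)
        np.testing.assert_allclose(s.translation, t, atol=1e-6)

    def test_matches_rotation_grid_oracle(self):
        assert kabsch(TOY_A, TOY_B).rmsd == pytest.approx(
            grid_search_rmsd(TOY_A, TOY_B), abs=1e-3
        )

    def test_proper_rotation_always(self, rng):
        # a mirrored target must still yield det +1
        a = rng.normal(size=(12, 3))
        b = a.copy()
        b[:, 0] = -b[:, 0]
        s = kabsch(a, b)
        assert np.linalg.det(s.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_symmetry_of_rmsd(self, rng):
        a, b = rng.normal(size=(30, 3)), rng.normal(size=(30, 3))
        assert kabsch(a, b).rmsd == pytest.approx(kabsch(b, a).rmsd, abs=1e-9)

    def test_rigid_invariance(self, rng):
        a, b = rng.normal(size=(20, 3)), rng.normal(size=(20, 3))
        r = random_rotation(rng)
        t = rng.normal(size=3) * 10
        base = kabsch(a, b).rmsd
        moved = kabsch(a @ r.T + t, b @ r.T + t).rmsd
        assert moved == pytest.approx(base, abs=1e-9)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            kabsch(TOY_A[:2], TOY_B[:2])

    def test_collinear_rejected(self):
        line = np.outer(np.arange(5.0), [1.0, 0.0, 0.0])
        with pytest.raises(DegenerateCoordinatesError):
            kabsch(line, line)

    def test_gaussian_noise_rmsd_law(self, rng):
        """Fitted RMSD approaches sigma*sqrt(3) for i.i.d. coordinate noise."""
        sigma = 0.5
        a = rng.normal(size=(2000, 3)) * 20
        b = a + rng.normal(scale=sigma, size=a.shape)
        assert kabsch(a, b).rmsd == pytest.approx(sigma * np.sqrt(3), rel=0.05)


class TestTrimmedSuperpose:
    def test_no_outliers_matches_kabsch(self, rng):
        a = rng.normal(size=(40, 3)) * 5
        b = a + rng.normal(scale=0.2, size=a.shape)
        plain, trimmed = kabsch(a, b), trimmed_superpose(a, b, 3.5)
        assert trimmed.rejected == []
        assert trimmed.rmsd == pytest.approx(plain.rmsd, abs=1e-12)

    def test_planted_outlier_rejected(self, rng):
        """One 10 A outlier among 50 perfect pairs is trimmed; the clean fit is recovered."""
        a = rng.normal(size=(51, 3)) * 8
        r = random_rotation(rng)
        b = a @ r.T
        b[17] += 10.0
        s = trimmed_superpose(a, b, reject_cutoff=3.5)
        assert s.n_pairs == 50
        assert s.rejected == [17]
        clean = kabsch(np.delete(a, 17, 0), np.delete(b, 17, 0))
        assert s.rmsd == pytest.approx(clean.rmsd, abs=1e-9)

    def test_rmsd_never_worse_than_kabsch(self, rng):
        a = rng.normal(size=(30, 3)) * 5
        b = a + rng.normal(scale=1.5, size=a.shape)
        assert trimmed_superpose(a, b, 2.0).rmsd <= kabsch(a, b).rmsd + 1e-12

    def test_all_rejected_is_error(self, rng):
        a = rng.normal(size=(10, 3))
        b = a + rng.normal(scale=30.0, size=a.shape)
        with pytest.raises(ValueError, match="retained"):
            trimmed_superpose(a, b, reject_cutoff=0.01)


def brute_force_lis(pairs):
    """All-subsets oracle for the longest order-preserving pair subset."""
    best = []
    for mask in range(1 << len(pairs)):
        sub = [pairs[i] for i in range(len(pairs)) if mask >> i & 1]
        if all(sub[k][1] < sub[k + 1][1] for k in range(len(sub) - 1)):
            if len(sub) > len(best):
                best = sub
    return len(best)


class TestCorrespondence:
    def test_identity_on_self(self):
        model, _ = synth_structure(30, ligand_atoms=0, seed=2)
        chain = model.chains[0]
        corr = correspondence_from_superposition(chain, chain, SuperpositionResult.identity())
        assert corr.pairs == [(i, i) for i in range(30)]

    def test_recovered_from_perturbed_copy(self):
        model, _ = synth_structure(60, ligand_atoms=0, seed=3)
        noisy = perturb_structure(model, 0.3, seed=4)
        corr = correspondence_from_superposition(
            model.chains[0], noisy.chains[0], SuperpositionResult.identity()
        )
        assert corr.pairs == [(i, i) for i in range(60)]

    def test_lis_filter_matches_brute_force(self, rng):
        for _ in range(20):
            k = int(rng.integers(1, 12))
            firsts = np.sort(rng.choice(50, size=k, replace=False))
            pairs = [(int(f), int(rng.integers(0, 50))) for f in firsts]
            dists = [float(rng.uniform(0.1, 2.0)) for _ in pairs]
            kept = _lis_pairs(pairs, dists)
            assert len(kept) == brute_force_lis(pairs)
            sub = [pairs[i] for i in kept]
            assert all(sub[i][1] < sub[i + 1][1] for i in range(len(sub) - 1))


class TestStructureAlignment:
    def test_rigid_copy_fully_paired(self, rng):
        model, _ = synth_structure(80, ligand_atoms=0, seed=5)
        moved = copy.deepcopy(model)
        r, t = random_rotation(rng), rng.normal(size=3) * 15
        for res in moved.all_residues():
            for atom in res.atoms:
                atom.coords = atom.coords @ r.T + t
        corr, sup = structure_alignment(model.chains[0], moved.chains[0])
        assert len(corr) == 80
        assert sup.rmsd == pytest.approx(0.0, abs=1e-9)

    def test_shared_core_with_divergent_tails(self, rng):
        """Only the rigidly shared 60-residue core should be paired."""
        model, _ = synth_structure(60, ligand_atoms=0, seed=6)
        a = copy.deepcopy(model)
        b = copy.deepcopy(model)
        # displace b far away rigidly, then append scrambled tails to both
        r, t = random_rotation(rng), np.array([40.0, -25.0, 60.0])
        for res in b.all_residues():
            for atom in res.atoms:
                atom.coords = atom.coords @ r.T + t
        tail_a, _ = synth_structure(20, ligand_atoms=0, seed=7)
        tail_b, _ = synth_structure(20, ligand_atoms=0, seed=8)
        for i, res in enumerate(tail_a.chains[0].residues):
            res.number = 61 + i
            for atom in res.atoms:
                atom.coords = atom.coords + np.array([-80.0, 0.0, 0.0])
            a.chains[0].residues.append(res)
        for i, res in enumerate(tail_b.chains[0].residues):
            res.number = 61 + i
            for atom in res.atoms:
                atom.coords = atom.coords @ r.T + t + np.array([80.0, 30.0, 0.0])
            b.chains[0].residues.append(res)
        corr, sup = structure_alignment(a.chains[0], b.chains[0])
        assert set(corr.pairs) == {(i, i) for i in range(60)}
        assert sup.rmsd == pytest.approx(0.0, abs=1e-6)

    def test_final_state_is_fixed_point(self):
        model, _ = synth_structure(70, ligand_atoms=0, seed=9)
        noisy = perturb_structure(model, 0.4, seed=10)
        corr, sup = structure_alignment(model.chains[0], noisy.chains[0])
        corr2 = correspondence_from_superposition(model.chains[0], noisy.chains[0], sup)
        assert len(corr2) == len(corr)
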