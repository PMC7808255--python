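import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from tyrcav import Structure, align_sequences, kabsch, prune_superpose
from tyrcav.superposition import superpose_structures

from conftest import make_atom

BLOSUM_DIAG = {"H": 8, "I": 4, "S": 4, "T": 5, "D": 6, "Y": 7, "R": 5,
               "A": 4, "C": 9, "E": 5, "F": 6}


def random_coords(n, seed):
    return np.random.default_rng(seed).normal(scale=8.0, size=(n, 3))


def rigid(coords, seed=0, angle_deg=40.0):
    rng = np.random.default_rng(seed)
    R = Rotation.from_rotvec(angle_deg * np.pi / 180 * rng.normal(size=3)).as_matrix()
    return coords @ R.T + rng.uniform(-10, 10, 3)


class TestAlignment:
    def test_identical_sequences_score_is_diagonal_sum(self):
        pairing = align_sequences("HISTDYR", "HISTDYR")
        assert len(pairing.pairs) == 7
        assert pairing.score == sum(BLOSUM_DIAG[c] for c in "HISTDYR")
        assert pairing.pairs == tuple((i, i) for i in range(7))

    def test_trivial_identity(self):
        assert len(align_sequences("ACD", "ACD").pairs) == 3

    def test_single_gap_alignment(self):
        # ACDEF vs ACEF: optimal is AC-EF with D gapped out of the short
        # sequence; score = S(A,A)+S(C,C)+gap+S(E,E)+S(F,F) = 4+9-11+5+6
        pairing = align_sequences("ACDEF", "ACEF")
        assert len(pairing.pairs) == 4
        assert pairing.score == 13
        assert pairing.pairs == ((0, 0), (1, 1), (3, 2), (4, 3))

    def test_illegal_character_names_position(self):
        with pytest.raises(ValueError, match="position 2"):
            align_sequences("AC1DEF", "ACDEF")

    def test_unknown_residue_tolerated(self):
        pairing = align_sequences("ACXDE", "ACXDE")
        assert len(pairing.pairs) == 5


class TestKabsch:
    def test_identity_gives_zero_rmsd(self):
        A = random_coords(12, 1)
        assert kabsch(A, A).rmsd_all == pytest.approx(0.0, abs=1e-9)

    def test_rigid_motion_recovered(self):
        A = random_coords(12, 2)
        Rz = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        B = A @ Rz.T + np.array([10.0, 0.0, 0.0])
        result = kabsch(A, B)
        assert result.rmsd_all == pytest.approx(0.0, abs=1e-9)
        # recovered transform undoes the motion
        np.testing.assert_allclose(result.rotation @ Rz, np.eye(3), atol=1e-6)
        assert np.linalg.det(result.rotation) == pytest.approx(1.0, abs=1e-6)

    def test_agrees_with_independent_solver(self):
        """Cross-check the fitted RMSD against scipy's orthogonal Procrustes."""
        A = random_coords(10, 3)
        B = A.copy()
        B[0] += np.array([0.0, 0.0, 3.0])
        mine = kabsch(A, B).rmsd_all
        _, rssd = Rotation.align_vectors(A - A.mean(0), B - B.mean(0))
        assert mine == pytest.approx(rssd / np.sqrt(10), rel=1e-9)

    def test_reflection_not_returned(self):
        A = random_coords(8, 4)
        B = A.copy()
        B[:, 0] *= -1  # mirrored input must still yield a proper rotation
        result = kabsch(A, B)
        assert np.linalg.det(result.rotation) == pytest.approx(1.0, abs=1e-6)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            kabsch(np.zeros((2, 3)), np.zeros((2, 3)))


class TestPrunedSuperposition:
    def test_identical_structures_no_pruning(self):
        A = random_coords(20, 5)
        result = prune_superpose(A, A.copy())
        assert result.rmsd_pruned == pytest.approx(0.0, abs=1e-9)
        assert result.rmsd_all == pytest.approx(0.0, abs=1e-9)
        assert result.retained_pairs == 20

    def test_outliers_pruned_at_cutoff(self):
        A = random_coords(20, 6)
        B = rigid(A, seed=6)
        B[3] += 5.0
        B[11] -= 5.0
        result = prune_superpose(A, B, cutoff=2.0)
        assert result.retained_pairs == 18
        assert result.rmsd_pruned == pytest.approx(0.0, abs=1e-6)
        assert result.rmsd_all > result.rmsd_pruned

    def test_all_within_cutoff_keeps_everything(self):
        A = random_coords(15, 7)
        B = A + np.random.default_rng(7).normal(scale=0.3, size=A.shape)
        result = prune_superpose(A, B, cutoff=2.0)
        assert result.retained_pairs == 15
        assert result.rmsd_pruned == pytest.approx(result.rmsd_all, rel=1e-9)

    def test_degraded_flag_when_floor_hit(self):
        A = random_coords(4, 8)
        B = A + np.random.default_rng(8).uniform(3.0, 6.0, size=A.shape)
        result = prune_superpose(A, B, cutoff=0.01)
        assert result.degraded
        assert result.retained_pairs >= 3

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_pruned_rmsd_never_exceeds_full_rmsd(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 30))
        A = rng.normal(scale=6.0, size=(n, 3))
        B = rigid(A, seed=seed) + rng.normal(scale=1.0, size=(n, 3))
        result = prune_superpose(A, B, cutoff=2.0)
        assert result.rmsd_pruned <= result.rmsd_all + 1e-9

    def test_structure_level_comparison(self):
        """Sequence pairing + CA superposition of a rigid copy gives RMSD 0."""
        rng = np.random.default_rng(17)
        residues = ["ALA", "GLY", "HIS", "SER", "TRP", "PHE", "LYS", "GLU"] * 3
        atoms = [
            make_atom(i + 1, rng.normal(scale=6.0, size=3), name="CA",
                      resname=res, resnum=i + 1)
            for i, res in enumerate(residues)
        ]
        a = Structure(atoms)
        b = a.transformed(
            Rotation.from_euler("xyz", [10, 60, -25], degrees=True).as_matrix(),
            (4.0, -2.0, 6.0),
        )
        result = superpose_structures(a, b)
        assert result.initial_pairs == len(residues)
        assert result.rmsd_pruned == pytest.approx(0.0, abs=1e-6)

    def test_invariant_under_pre_rotation(self):
        A = random_coords(14, 9)
        B = rigid(A, seed=9) + np.random.default_rng(9).normal(scale=0.5, size=(14, 3))
        r0 = prune_superpose(A, B).rmsd_pruned
        r1 = prune_superpose(A, rigid(B, seed=123)).rmsd_pruned
        assert r0 == pytest.approx(r1, abs=1e-6)
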