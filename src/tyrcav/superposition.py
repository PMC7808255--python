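"""Sequence-based residue pairing, Kabsch superposition, and pruned RMSD.

Structure comparison proceeds the way interactive matchmaking tools do:
pair residues of the two chains by global sequence alignment
(Needleman–Wunsch, BLOSUM-62, affine gaps), superimpose the CA atoms of
paired residues with the least-squares (Kabsch) fit, then iterate —
dropping every pair farther apart than a cutoff (2.0 Å by default) and
refitting — until no pair exceeds the cutoff. The result reports both the
RMSD over the retained pairs and the RMSD over all initial pairs under the
final transform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .structure_io import Structure

__all__ = [
    "ResiduePairing",
    "SuperpositionResult",
    "align_sequences",
    "kabsch",
    "prune_superpose",
    "superpose_structures",
    "ca_coordinates",
    "structure_sequence",
]

_AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

_VALID_LETTERS = set("ACDEFGHIKLMNPQRSTVWYX")


@dataclass(frozen=True, slots=True)
class ResiduePairing:
    """One-to-one, order-preserving residue pairs from a global alignment."""

    pairs: tuple[tuple[int, int], ...]
    score: float


@dataclass(slots=True)
class SuperpositionResult:
    rotation: np.ndarray
    translation: np.ndarray
    rmsd_all: float
    rmsd_pruned: float | None = None
    retained_pairs: int = 0
    initial_pairs: int = 0
    degraded: bool = False  # pruning hit the 3-pair floor


def _make_aligner(gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    matrix = substitution_matrices.load("BLOSUM62")
    matrix = matrix.copy()
    # unknown residues pair neutrally
    for letter in matrix.alphabet:
        matrix["X", letter] = 0.0
        matrix[letter, "X"] = 0.0
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def align_sequences(
    seq_a: str,
    seq_b: str,
    gap_open: float = -11.0,
    gap_extend: float = -1.0,
) -> ResiduePairing:
    """Global Needleman–Wunsch alignment under BLOSUM-62 with affine gaps.

    Returns residue index pairs (0-based into each sequence) for aligned,
    non-gap columns, and the alignment score. ``X`` is tolerated and scored
    0 against everything.
    """
    for label, seq in (("seq_a", seq_a), ("seq_b", seq_b)):
        if not seq:
            raise ValueError(f"{label} is empty")
        for pos, ch in enumerate(seq):
            if ch.upper() not in _VALID_LETTERS:
                raise ValueError(
                    f"illegal character {ch!r} at position {pos} of {label}"
                )
    aligner = _make_aligner(gap_open, gap_extend)
    alignment = aligner.align(seq_a.upper(), seq_b.upper())[0]
    pairs: list[tuple[int, int]] = []
    for (a_start, a_end), (b_start, b_end) in zip(*alignment.aligned):
        pairs.extend(
            (ai, bi) for ai, bi in zip(range(a_start, a_end), range(b_start, b_end))
        )
    return ResiduePairing(pairs=tuple(pairs), score=float(alignment.score))


def kabsch(coords_a: np.ndarray, coords_b: np.ndarray) -> SuperpositionResult:
    """Least-squares rigid superposition of B onto A.

    Returns the rotation/translation mapping ``coords_b`` onto
    ``coords_a`` (x_b -> R x_b + t) and the RMSD over all pairs. The
    reflection case is handled by the usual determinant sign correction,
    so the rotation is always proper (det = +1).
    """
    A = np.asarray(coords_a, dtype=float)
    B = np.asarray(coords_b, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise ValueError("coordinate arrays must both be N x 3")
    n = A.shape[0]
    if n < 3:
        raise ValueError("superposition needs at least 3 atom pairs")
    ca, cb = A.mean(axis=0), B.mean(axis=0)
    H = (B - cb).T @ (A - ca)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ca - R @ cb
    moved = B @ R.T + t
    rmsd = float(np.sqrt(((moved - A) ** 2).sum(axis=1).mean()))
    return SuperpositionResult(
        rotation=R,
        translation=t,
        rmsd_all=rmsd,
        retained_pairs=n,
        initial_pairs=n,
    )


def prune_superpose(
    coords_a: np.ndarray,
    coords_b: np.ndarray,
    cutoff: float = 2.0,
    max_iterations: int = 100,
    one_at_a_time: bool = False,
) -> SuperpositionResult:
    """Iteratively pruned superposition.

    Fit, then drop pairs whose post-fit separation exceeds ``cutoff`` and
    refit, until no pair exceeds the cutoff (or fewer than 3 pairs would
    remain, in which case the last valid fit is kept and the result is
    flagged ``degraded``). By default all offending pairs are dropped each
    iteration; ``one_at_a_time`` removes only the single worst pair per
    iteration.

    ``rmsd_pruned`` is the RMSD over the retained pairs; ``rmsd_all`` is
    the RMSD over *all* initial pairs under the final transform.
    """
    A = np.asarray(coords_a, dtype=float)
    B = np.asarray(coords_b, dtype=float)
    if A.shape != B.shape:
        raise ValueError("coordinate arrays must match in shape")
    n = A.shape[0]
    if n < 3:
        raise ValueError("pruned superposition needs at least 3 initial pairs")
    keep = np.ones(n, dtype=bool)
    result = kabsch(A, B)
    degraded = False
    for _ in range(max_iterations):
        fit = kabsch(A[keep], B[keep])
        moved = B @ fit.rotation.T + fit.translation
        dist = np.linalg.norm(moved - A, axis=1)
        result = fit
        offenders = keep & (dist > cutoff)
        if not offenders.any():
            break
        if one_at_a_time:
            worst = np.argmax(np.where(offenders, dist, -np.inf))
            candidate = keep.copy()
            candidate[worst] = False
        else:
            candidate = keep & ~offenders
        if candidate.sum() < 3:
            degraded = True
            break
        keep = candidate
    moved = B @ result.rotation.T + result.translation
    dist_all = np.linalg.norm(moved - A, axis=1)
    return SuperpositionResult(
        rotation=result.rotation,
        translation=result.translation,
        rmsd_all=float(np.sqrt((dist_all**2).mean())),
        rmsd_pruned=float(np.sqrt((dist_all[keep] ** 2).mean())),
        retained_pairs=int(keep.sum()),
        initial_pairs=n,
        degraded=degraded,
    )


def structure_sequence(structure: Structure) -> tuple[str, list[tuple[str, int]]]:
    """One-letter sequence of the CA trace plus the residue keys behind it."""
    seq = []
    keys = []
    for a in structure.atoms:
        if a.name != "CA" or a.is_hetero:
            continue
        seq.append(_AA3_TO_1.get(a.residue_name.upper(), "X"))
        keys.append((a.chain_id, a.residue_number))
    return "".join(seq), keys


def ca_coordinates(structure: Structure) -> np.ndarray:
    """Coordinates of the CA trace in residue order."""
    return np.array(
        [a.coordinates for a in structure.atoms if a.name == "CA" and not a.is_hetero],
        dtype=float,
    )


def superpose_structures(
    structure_a: Structure,
    structure_b: Structure,
    cutoff: float = 2.0,
    gap_open: float = -11.0,
    gap_extend: float = -1.0,
) -> SuperpositionResult:
    """Full comparison: align sequences, pair CAs, prune-superpose."""
    seq_a, _ = structure_sequence(structure_a)
    seq_b, _ = structure_sequence(structure_b)
    pairing = align_sequences(seq_a, seq_b, gap_open, gap_extend)
    ca_a = ca_coordinates(structure_a)
    ca_b = ca_coordinates(structure_b)
    idx_a = [i for i, _ in pairing.pairs]
    idx_b = [j for _, j in pairing.pairs]
    return prune_superpose(ca_a[idx_a], ca_b[idx_b], cutoff=cutoff)
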