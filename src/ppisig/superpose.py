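"""Rigid-body superposition and structure-guided residue correspondence.

The elementary fit is the Kabsch least-squares superposition (via
``scipy.spatial.transform.Rotation.align_vectors``, which already excludes
improper rotations).  On top of it sit an iterative outlier-trimming fit,
mutual-nearest-neighbour residue pairing constrained to sequential order,
and an alternating align/fit loop that produces a structure-based pairing
of two homologous chains without any external alignment program.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .model_io import ChainModel

__all__ = [
    "SuperpositionResult",
    "PairCorrespondence",
    "kabsch",
    "trimmed_superpose",
    "correspondence_from_superposition",
    "structure_alignment",
    "DegenerateCoordinatesError",
]

DEFAULT_REJECT_CUTOFF = 3.5  # Angstrom, Calpha deviation above which a pair is trimmed
DEFAULT_PAIR_CUTOFF = 3.8    # Angstrom, conventional Calpha-Calpha contact scale


class DegenerateCoordinatesError(ValueError):
    """Raised when a point set does not determine a unique rotation."""


@dataclass
class SuperpositionResult:
    rotation: np.ndarray      # 3x3 proper rotation
    translation: np.ndarray   # 3-vector, Angstrom
    rmsd: float
    n_pairs: int
    rejected: list[int] = field(default_factory=list)  # indices into the input pairing

    def apply(self, coords: np.ndarray) -> np.ndarray:
        """Map coordinates from frame a into frame b."""
        return np.asarray(coords, float) @ self.rotation.T + self.translation

    @staticmethod
    def identity() -> "SuperpositionResult":
        return SuperpositionResult(np.eye(3), np.zeros(3), 0.0, 0)


@dataclass
class PairCorrespondence:
    pairs: list[tuple[int, int]]
    anchor_atom: str = "CA"

    def __len__(self) -> int:
        return len(self.pairs)


def _check_not_collinear(coords: np.ndarray, label: str) -> None:
    centered = coords - coords.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[0] == 0 or sv[1] / sv[0] < 1e-8:
        raise DegenerateCoordinatesError(
            f"{label}: points are collinear; rotation is not uniquely determined"
        )


def kabsch(coords_a: np.ndarray, coords_b: np.ndarray) -> SuperpositionResult:
    """Least-squares rigid superposition of ``coords_a`` onto ``coords_b``.

    Points are paired by index.  Returns the proper rotation R and
    translation t minimising RMSD of ``R a + t`` against ``b``.
    """
    a = np.asarray(coords_a, float)
    b = np.asarray(coords_b, float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("coordinate arrays must be matching (N, 3)")
    n = a.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 paired points, got {n}")
    _check_not_collinear(a, "set a")
    _check_not_collinear(b, "set b")

    ca, cb = a.mean(axis=0), b.mean(axis=0)
    rot, rssd = Rotation.align_vectors(b - cb, a - ca)
    r = rot.as_matrix()
    t = cb - r @ ca
    return SuperpositionResult(rotation=r, translation=t, rmsd=float(rssd) / np.sqrt(n), n_pairs=n)


def trimmed_superpose(
    coords_a: np.ndarray,
    coords_b: np.ndarray,
    reject_cutoff: float = DEFAULT_REJECT_CUTOFF,
    max_cycles: int = 10,
) -> SuperpositionResult:
    """Iterative superposition with rejection of deviating pairs.

    Refits on the retained pairs and rejects any pair whose post-fit
    deviation exceeds ``reject_cutoff`` until no rejection occurs or
    ``max_cycles`` is reached.  The final RMSD is over retained pairs only.
    """
    a = np.asarray(coords_a, float)
    b = np.asarray(coords_b, float)
    retained = np.arange(a.shape[0])
    sup = kabsch(a, b)
    for _ in range(max_cycles):
        dev = np.linalg.norm(sup.apply(a[retained]) - b[retained], axis=1)
        keep = dev <= reject_cutoff
        if keep.all():
            break
        retained = retained[keep]
        if retained.size < 3:
            raise ValueError("no pairs retained after trimming")
        sup = kabsch(a[retained], b[retained])
    rejected = sorted(set(range(a.shape[0])) - set(retained.tolist()))
    return SuperpositionResult(sup.rotation, sup.translation, sup.rmsd, int(retained.size), rejected)


def _lis_pairs(
    pairs: list[tuple[int, int]], dists: list[float]
) -> list[int]:
    """Longest subset of pairs increasing in both columns.

    Pairs must be sorted by the first column (strictly increasing).  Ties in
    length are broken by the smaller summed pair distance, which makes the
    selection deterministic.  O(k^2) dynamic program.
    """
    k = len(pairs)
    if k == 0:
        return []
    best_len = [1] * k
    best_sum = list(dists)
    prev = [-1] * k
    for i in range(k):
        for j in range(i):
            if pairs[j][1] < pairs[i][1]:
                cand_len = best_len[j] + 1
                cand_sum = best_sum[j] + dists[i]
                if cand_len > best_len[i] or (
                    cand_len == best_len[i] and cand_sum < best_sum[i]
                ):
                    best_len[i] = cand_len
                    best_sum[i] = cand_sum
                    prev[i] = j
    end = max(range(k), key=lambda i: (best_len[i], -best_sum[i]))
    out = []
    while end != -1:
        out.append(end)
        end = prev[end]
    return out[::-1]


def correspondence_from_superposition(
    chain_a: ChainModel,
    chain_b: ChainModel,
    sup: SuperpositionResult,
    pair_cutoff: float = DEFAULT_PAIR_CUTOFF,
    anchor: str = "CA",
) -> PairCorrespondence:
    """Residue pairing implied by a superposition.

    Pairs mutual nearest anchor atoms within ``pair_cutoff`` after mapping
    chain a into chain b's frame, then keeps the longest order-preserving
    subset so the pairing respects sequence direction in both chains.
    """
    xa, ia = chain_a.anchor_coords(anchor)
    xb, ib = chain_b.anchor_coords(anchor)
    if len(ia) < 3 or len(ib) < 3:
        raise ValueError("both chains need at least 3 anchor atoms")
    xa = sup.apply(xa)
    tree_a, tree_b = cKDTree(xa), cKDTree(xb)
    d_ab, nn_ab = tree_b.query(xa, k=1)
    _, nn_ba = tree_a.query(xb, k=1)
    cand: list[tuple[int, int]] = []
    dists: list[float] = []
    for i in range(len(ia)):
        j = int(nn_ab[i])
        if d_ab[i] <= pair_cutoff and int(nn_ba[j]) == i:
            cand.append((ia[i], ib[j]))
            dists.append(float(d_ab[i]))
    keep = _lis_pairs(cand, dists)
    return PairCorrespondence(pairs=[cand[i] for i in keep], anchor_atom=anchor)


def _robust_fit(a: np.ndarray, b: np.ndarray, reject_cutoff: float) -> SuperpositionResult:
    """Fit discarding the single worst pair until all deviations pass.

    Unlike the batch rule of :func:`trimmed_superpose`, removing one pair at
    a time stays stable even when a minority of wildly wrong pairs (e.g.
    divergent tails in a sequence-alignment seed) dominates the initial
    least-squares frame.
    """
    retained = np.arange(a.shape[0])
    while True:
        sup = kabsch(a[retained], b[retained])
        dev = np.linalg.norm(sup.apply(a[retained]) - b[retained], axis=1)
        worst = int(np.argmax(dev))
        if dev[worst] <= reject_cutoff:
            rejected = sorted(set(range(a.shape[0])) - set(retained.tolist()))
            return SuperpositionResult(sup.rotation, sup.translation, sup.rmsd,
                                       int(retained.size), rejected)
        if retained.size <= 3:
            raise ValueError("no pairs retained after trimming")
        retained = np.delete(retained, worst)


def _seed_from_sequence(chain_a: ChainModel, chain_b: ChainModel, anchor: str) -> PairCorrespondence:
    from .discovery import global_align  # local import: discovery does not import superpose

    aln = global_align(chain_a.sequence, chain_b.sequence)
    pairs = [(i - 1, j - 1) for i, j in aln.map_ab.items() if j is not None]
    # restrict to residues that actually carry the anchor atom
    _, ia = chain_a.anchor_coords(anchor)
    _, ib = chain_b.anchor_coords(anchor)
    sa, sb = set(ia), set(ib)
    pairs = [(i, j) for i, j in pairs if i in sa and j in sb]
    if not pairs:
        raise ValueError("sequence alignment produced no seed pairs")
    return PairCorrespondence(pairs=pairs, anchor_atom=anchor)


def structure_alignment(
    chain_a: ChainModel,
    chain_b: ChainModel,
    seed: PairCorrespondence | str = "sequence",
    pair_cutoff: float = DEFAULT_PAIR_CUTOFF,
    reject_cutoff: float = DEFAULT_REJECT_CUTOFF,
    max_cycles: int = 20,
    anchor: str = "CA",
) -> tuple[PairCorrespondence, SuperpositionResult]:
    """Iterative structure-based pairing of two homologous chains.

    Alternates between fitting a trimmed superposition on the current
    residue pairing and rebuilding the pairing from the fit, until the pair
    count is unchanged and the RMSD moves by less than 0.01 A, or
    ``max_cycles``.  The per-cycle fit trims pairs deviating by more than
    ``reject_cutoff`` so that a seed polluted by non-equivalent residues
    (e.g. divergent tails in a sequence alignment) cannot skew the frame.
    The default seed pairing comes from a global sequence alignment.
    """
    if len(chain_a.amino_residues()) < 20 or len(chain_b.amino_residues()) < 20:
        raise ValueError("structure alignment needs chains of at least 20 residues")
    corr = seed if isinstance(seed, PairCorrespondence) else _seed_from_sequence(chain_a, chain_b, anchor)

    res_a = chain_a.amino_residues()
    res_b = chain_b.amino_residues()

    def _fit(c: PairCorrespondence) -> SuperpositionResult:
        pa = np.array([res_a[i].get_atom(anchor).coords for i, _ in c.pairs])
        pb = np.array([res_b[j].get_atom(anchor).coords for _, j in c.pairs])
        return _robust_fit(pa, pb, reject_cutoff)

    sup = _fit(corr)
    prev = (len(corr), sup.rmsd)
    for _ in range(max_cycles):
        corr_new = correspondence_from_superposition(chain_a, chain_b, sup, pair_cutoff, anchor)
        if len(corr_new) < 3:
            break
        sup = _fit(corr_new)
        corr = corr_new
        cur = (len(corr), sup.rmsd)
        if cur[0] == prev[0] and abs(cur[1] - prev[1]) < 0.01:
            break
        prev = cur
    return corr, sup
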