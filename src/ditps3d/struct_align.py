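"""Shell extraction and TM-score structural superposition.

Two structural comparisons drive the analysis: global fold similarity of
whole enzymes, and local similarity of the "shells" of residues surrounding
the bound substrate.  Both are scored with the TM-score,

    TM = (1 / L_norm) * sum_i 1 / (1 + (d_i / d0(L_norm))^2),

where d_i are distances over aligned residue pairs after optimal rigid
superposition and d0(L) = 1.24 * (L - 15)^(1/3) - 1.8 (clamped below at
0.5 A) is the standard length normalization.  Because TM is asymmetric in
the normalizing length, both normalizations are computed and their mean is
used as the scalar similarity in matrices.

The aligner here is a compact sequence-order-dependent TM iterator: seed
correspondences from gapless threading of fragments, then alternate rigid
superposition on the current pairs with dynamic programming over the TM
kernel score matrix until the pair set converges.  Shells are compared with
the same aligner, keeping residues in chain order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .io_model import LigandPose, Residue, ResidueShell, StructureModel
from .seq_analysis import SimilarityMatrix

__all__ = [
    "d0",
    "extract_shell",
    "kabsch",
    "tm_score",
    "tm_superpose",
    "StructAlignment",
    "align_structures",
    "shell_tm_matrix",
    "global_tm_matrix",
]


def d0(l_norm: int) -> float:
    """TM-score distance scale d0(L), clamped below at 0.5 A."""
    if l_norm < 1:
        raise ValueError("L_norm must be >= 1")
    if l_norm <= 15:
        return 0.5
    return max(0.5, 1.24 * (l_norm - 15) ** (1.0 / 3.0) - 1.8)


# ---------------------------------------------------------------------------
# shell extraction


def extract_shell(
    structure: StructureModel, ligand: LigandPose, radius_A: float
) -> ResidueShell:
    """Whole residues with any heavy atom within ``radius_A`` of any ligand atom.

    Implements the PyMOL ``byres all within r`` selection: the distance test
    is atom-to-atom (inclusive, <= r) but whole residues are retained, in
    parent chain order.  An empty intersection yields an empty shell with a
    warning.
    """
    if radius_A <= 0:
        raise ValueError("radius must be positive")
    lig = ligand.coords()
    members = [
        res
        for res in structure.residues
        if cdist(res.coords(), lig).min() <= radius_A
    ]
    if not members:
        warnings.warn(
            f"{structure.structure_id}: no residues within {radius_A} A of ligand"
        )
    return ResidueShell(
        structure_id=structure.structure_id, radius_A=radius_A, residues=members
    )


# ---------------------------------------------------------------------------
# rigid superposition


def kabsch(
    coords_a: np.ndarray, coords_b: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of ``coords_a`` onto ``coords_b``.

    Returns ``(rotation, translation, rmsd)`` with the proper rotation
    (det = +1) minimizing || R a_i + t - b_i ||.  Requires >= 3 points that
    are not collinear.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("coordinate arrays must be matching (n, 3)")
    if len(a) < 3:
        raise ValueError("kabsch needs at least 3 points")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    a0, b0 = a - ca, b - cb
    if np.linalg.matrix_rank(a0, tol=1e-8) < 2 or np.linalg.matrix_rank(b0, tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) geometry")
    h = a0.T @ b0
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rot = vt.T @ diag @ u.T
    trans = cb - rot @ ca
    diff = (a @ rot.T + trans) - b
    rmsd = float(np.sqrt((diff**2).sum() / len(a)))
    return rot, trans, rmsd


def tm_score(
    pairs: Sequence[tuple[int, int]],
    coords_a: np.ndarray,
    coords_b: np.ndarray,
    l_norm: int,
) -> float:
    """TM-score of already-superposed coordinates over aligned pairs."""
    if l_norm < 1:
        raise ValueError("L_norm must be >= 1")
    if not len(pairs):
        return 0.0
    ia, ib = zip(*pairs)
    d = np.linalg.norm(
        np.asarray(coords_a, float)[list(ia)] - np.asarray(coords_b, float)[list(ib)],
        axis=1,
    )
    return float(np.sum(1.0 / (1.0 + (d / d0(l_norm)) ** 2)) / l_norm)


def tm_superpose(
    pa: np.ndarray, pb: np.ndarray, l_norm: int
) -> tuple[float, np.ndarray, np.ndarray]:
    """Transform maximizing TM for a fixed one-to-one correspondence.

    ``pa[i]`` corresponds to ``pb[i]``.  Follows the classic TM-score
    strategy: superpose on sliding sub-fragments of several lengths, then
    iteratively re-superpose on the pairs closer than a distance cutoff,
    keeping the transform with the best TM.  Returns (tm, rotation,
    translation) with the transform applying to ``pa``.
    """
    pa = np.asarray(pa, float)
    pb = np.asarray(pb, float)
    n = len(pa)
    if n < 3:
        raise ValueError("need >= 3 paired points")
    cut = max(d0(l_norm), 1.0)
    best = (-1.0, np.eye(3), np.zeros(3))
    frag_lengths = sorted({n, max(3, n // 2), min(n, 5)}, reverse=True)
    for fl in frag_lengths:
        step = max(1, fl // 2)
        for start in range(0, n - fl + 1, step):
            sel = np.arange(start, start + fl)
            for _ in range(12):
                try:
                    rot, trans, _ = kabsch(pa[sel], pb[sel])
                except ValueError:
                    break
                d = np.linalg.norm((pa @ rot.T + trans) - pb, axis=1)
                tm = float(np.sum(1.0 / (1.0 + (d / d0(l_norm)) ** 2)) / l_norm)
                if tm > best[0]:
                    best = (tm, rot, trans)
                new_sel = np.where(d < cut)[0]
                if len(new_sel) < 3 or np.array_equal(new_sel, sel):
                    break
                sel = new_sel
    return best


# ---------------------------------------------------------------------------
# sequence-order-dependent TM alignment

GAP_PENALTY = -0.6  # opening penalty in DP over the TM kernel; extension free


@dataclass
class StructAlignment:
    """Result of a pairwise structural alignment."""

    pairs: list[tuple[int, int]]
    rotation: np.ndarray
    translation: np.ndarray
    rmsd_A: float
    tm_by_A: float
    tm_by_B: float

    @property
    def tm_mean(self) -> float:
        return 0.5 * (self.tm_by_A + self.tm_by_B)


def _kernel_matrix(pa: np.ndarray, pb: np.ndarray, dd0: float) -> np.ndarray:
    d = cdist(pa, pb)
    return 1.0 / (1.0 + (d / dd0) ** 2)


def _dp_pairs(score: np.ndarray) -> list[tuple[int, int]]:
    """Global DP over a similarity score matrix; gap opening -0.6, extension free.

    Three-state Gotoh, row-vectorized.  The traceback recomputes the forward
    candidates with the identical float expressions, so exact equality picks
    the path deterministically (priority: match > gap-in-B > gap-in-A).
    Returns pairs strictly increasing in both indices.
    """
    n, m = score.shape
    neg = -1e30
    g = GAP_PENALTY
    M = np.full((n + 1, m + 1), neg)  # a[i-1] aligned to b[j-1]
    X = np.full((n + 1, m + 1), neg)  # gap in B (rows consumed)
    Y = np.full((n + 1, m + 1), neg)  # gap in A (cols consumed)
    M[0, 0] = 0.0
    Y[0, 1:] = g  # leading gap in A
    for i in range(1, n + 1):
        prev_best = np.maximum(np.maximum(M[i - 1], X[i - 1]), Y[i - 1])
        M[i, 1:] = prev_best[:-1] + score[i - 1]
        X[i] = np.maximum(np.maximum(M[i - 1], Y[i - 1]) + g, X[i - 1])
        b = np.maximum(M[i], X[i]) + g
        Y[i, 1:] = np.maximum.accumulate(b)[:-1]
    i, j = n, m
    cand = (M[i, j], X[i, j], Y[i, j])
    state = min(s for s in range(3) if cand[s] == max(cand))
    pairs: list[tuple[int, int]] = []
    while i > 0 or j > 0:
        if state == 0:
            pairs.append((i - 1, j - 1))
            i, j = i - 1, j - 1
            cand = (M[i, j], X[i, j], Y[i, j])
            state = min(s for s in range(3) if cand[s] == max(cand))
        elif state == 1:  # gap in B: step up one row
            v = X[i, j]
            i -= 1
            if M[i, j] + g == v:
                state = 0
            elif Y[i, j] + g == v:
                state = 2
            else:
                state = 1
        else:  # gap in A: step left one column
            j -= 1
            v = Y[i, j + 1]
            if max(M[i, j], X[i, j]) + g == v:
                state = 0 if M[i, j] >= X[i, j] else 1
            else:
                state = 2
    pairs.reverse()
    return pairs


def _ca_and_id(obj: StructureModel | ResidueShell) -> tuple[np.ndarray, str]:
    sid = obj.structure_id
    ca = obj.ca_coords()
    return np.asarray(ca, float), sid


def align_structures(
    a: StructureModel | ResidueShell,
    b: StructureModel | ResidueShell,
    max_iter: int = 30,
) -> StructAlignment:
    """Sequence-order-dependent structural alignment maximizing the TM-score.

    Correspondences are seeded by gapless threading of fragments (lengths 5,
    half, and full of the shorter chain); each seed is refined by alternating
    (i) rigid superposition on the close pairs and (ii) DP over the TM kernel
    score matrix, until the pair set repeats or ``max_iter`` iterations.  The
    best pair set by TM (normalized by the shorter length) is kept, then both
    normalizations are scored with their own TM-optimal superposition.
    """
    pa, sid_a = _ca_and_id(a)
    pb, sid_b = _ca_and_id(b)
    la, lb = len(pa), len(pb)
    if la < 4 or lb < 4:
        raise ValueError(f"too small to align: {sid_a} ({la}) vs {sid_b} ({lb})")
    lmin = min(la, lb)
    dd0 = d0(lmin)
    cut = max(dd0, 1.0)

    def refine(seed_pairs: list[tuple[int, int]]) -> tuple[float, list[tuple[int, int]]]:
        pairs = seed_pairs
        seen: set[tuple] = set()
        best_tm, best_pairs = -1.0, pairs
        for _ in range(max_iter):
            key = tuple(pairs)
            if key in seen or len(pairs) < 3:
                break
            seen.add(key)
            ia = [p[0] for p in pairs]
            ib = [p[1] for p in pairs]
            try:
                rot, trans, _ = kabsch(pa[ia], pb[ib])
            except ValueError:
                break
            moved = pa @ rot.T + trans
            d = np.linalg.norm(moved[ia] - pb[ib], axis=1)
            close = d < cut
            if close.sum() >= 3 and close.sum() < len(pairs):
                try:
                    rot, trans, _ = kabsch(pa[np.array(ia)[close]], pb[np.array(ib)[close]])
                    moved = pa @ rot.T + trans
                except ValueError:
                    pass
            tm_here = tm_score(pairs, moved, pb, lmin)
            if tm_here > best_tm:
                best_tm, best_pairs = tm_here, pairs
            pairs = _dp_pairs(_kernel_matrix(moved, pb, dd0))
        return best_tm, best_pairs

    # seeds: gapless diagonal threading at sampled shifts, plus short and
    # half-length windows along the zero-shift diagonal
    seeds: list[list[tuple[int, int]]] = []
    shifts = sorted({int(s) for s in np.linspace(-(la - 4), lb - 4, num=9)} | {0})
    for shift in shifts:
        lo = max(0, -shift)
        hi = min(la, lb - shift)
        if hi - lo >= 3:
            seeds.append([(i, i + shift) for i in range(lo, hi)])
    for fl in sorted({min(5, lmin), max(3, lmin // 2)}):
        for off in range(0, lmin - fl + 1, max(1, (lmin - fl) // 4 or 1)):
            seeds.append([(off + k, off + k) for k in range(fl)])
    best_tm, best_pairs = -1.0, []
    for seed in seeds:
        tm_here, pairs_here = refine(seed)
        if tm_here > best_tm:
            best_tm, best_pairs = tm_here, pairs_here
    if not best_pairs:
        raise ValueError(f"alignment failed: {sid_a} vs {sid_b}")
    ia = [p[0] for p in best_pairs]
    ib = [p[1] for p in best_pairs]
    tm_a, _, _ = tm_superpose(pa[ia], pb[ib], la)
    tm_b, rot_b, trans_b = tm_superpose(pa[ia], pb[ib], lb)
    rot, trans, rmsd = kabsch(pa[ia], pb[ib])
    return StructAlignment(
        pairs=best_pairs,
        rotation=rot,
        translation=trans,
        rmsd_A=rmsd,
        tm_by_A=tm_a,
        tm_by_B=tm_b,
    )


# ---------------------------------------------------------------------------
# matrices


def _tm_matrix(objs: dict[str, StructureModel | ResidueShell], kind: str) -> SimilarityMatrix:
    ids = list(objs)
    n = len(ids)
    vals = np.full((n, n), np.nan)
    usable = {i for i, sid in enumerate(ids) if len(objs[sid].ca_coords()) >= 4}
    for i in range(n):
        if i in usable:
            vals[i, i] = 1.0
        for j in range(i + 1, n):
            if i in usable and j in usable:
                aln = align_structures(objs[ids[i]], objs[ids[j]])
                vals[i, j] = vals[j, i] = aln.tm_mean
    if np.isnan(vals).all():
        raise ValueError("no pair of structures was alignable")
    return SimilarityMatrix(ids=ids, values=vals, kind=kind, scale="unit")


def shell_tm_matrix(shells: dict[str, ResidueShell], radius_A: float) -> SimilarityMatrix:
    """Pairwise mean TM-score matrix over substrate shells at one radius.

    Shells with fewer than 4 residues are recorded as missing (NaN rows).
    """
    return _tm_matrix(dict(shells), kind=f"tm_shell_{int(radius_A)}")


def global_tm_matrix(structures: dict[str, StructureModel]) -> SimilarityMatrix:
    """Pairwise mean TM-score matrix over whole structures."""
    return _tm_matrix(dict(structures), kind="tm_global")
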