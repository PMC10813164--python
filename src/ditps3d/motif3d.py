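"""Sequence-order-independent 3D motifs of substrate-surrounding residues.

A 3D motif is a set of residues with conserved identities and conserved
mutual C-alpha geometry that recurs across active sites regardless of where
the residues sit in the sequence.  The workflow has three steps:

1. :func:`align_sites` — multi-site correspondence of substrate shells.
   Residues are described by their sorted vector of intra-shell C-alpha
   distances (an order-free descriptor), candidate matches are scored by
   descriptor agreement plus an identity bonus, resolved by Hungarian
   assignment, and refined by iterative rigid superposition.
2. :func:`extract_motif` — columns that are both well-covered across sites
   and geometrically tight become motif positions, gated by the two
   representativeness cutoffs (coverage > 0.6, tightness > 0.4 by default).
3. :func:`search_motif` — find the motif in a query structure by residue
   identity (strict, or relaxed allowing one mutation), pairwise-distance
   pruning against the template geometry, and final RMSD screening.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from .io_model import ResidueShell, StructureModel
from .struct_align import kabsch

__all__ = [
    "SiteAlignment",
    "Motif3D",
    "MotifMatch",
    "align_sites",
    "extract_motif",
    "conservation_profile",
    "search_motif",
]

DESCRIPTOR_TOL_A = 1.5  # distance-entry agreement tolerance in the descriptor match
IDENTITY_BONUS = 0.2
REFINE_DROP_A = 3.0  # pairs deviating more than this after superposition are dropped
REFINE_ROUNDS = 10


@dataclass
class SiteAlignment:
    """Residue correspondences of several binding sites against a reference.

    ``columns[c]`` is the reference residue key of column ``c``;
    ``matches[site_id][c]`` is the matched residue index in that site's shell
    (or None for a gap).  ``agreement[c]`` is the mean final pair score of
    the column across sites, in [0, 1]; ``deviations[c]`` the mean C-alpha
    deviation (A) of matched residues after superposition.
    """

    reference_id: str
    reference_shell: ResidueShell
    site_ids: list[str]
    matches: dict[str, list[int | None]]
    agreement: np.ndarray
    deviations: np.ndarray
    shells: dict[str, ResidueShell]

    @property
    def columns(self) -> list[tuple[str, int, str]]:
        return self.reference_shell.residue_keys

    @property
    def n_columns(self) -> int:
        return len(self.reference_shell)

    def column_letters(self, c: int) -> list[str]:
        """Residue letters observed in column ``c`` (reference + matches)."""
        letters = [self.reference_shell.residues[c].letter]
        for sid in self.site_ids:
            idx = self.matches[sid][c]
            if idx is not None:
                letters.append(self.shells[sid].residues[idx].letter)
        return letters


def _descriptors(coords: np.ndarray) -> list[np.ndarray]:
    d = cdist(coords, coords)
    return [np.sort(np.delete(d[i], i)) for i in range(len(coords))]


def _greedy_fraction(da: np.ndarray, db: np.ndarray, tol: float) -> float:
    """Fraction of descriptor entries matched greedily within ``tol``."""
    i = j = matched = 0
    while i < len(da) and j < len(db):
        diff = da[i] - db[j]
        if abs(diff) <= tol:
            matched += 1
            i += 1
            j += 1
        elif diff < 0:
            i += 1
        else:
            j += 1
    return matched / max(len(da), len(db))


def _pair_scores(shell_a: ResidueShell, shell_b: ResidueShell) -> np.ndarray:
    ca, cb = shell_a.ca_coords(), shell_b.ca_coords()
    desc_a, desc_b = _descriptors(ca), _descriptors(cb)
    la = [r.letter for r in shell_a.residues]
    lb = [r.letter for r in shell_b.residues]
    s = np.zeros((len(ca), len(cb)))
    for i, da in enumerate(desc_a):
        for j, db in enumerate(desc_b):
            v = _greedy_fraction(da, db, DESCRIPTOR_TOL_A)
            if la[i] == lb[j]:
                v = min(1.0, v + IDENTITY_BONUS)
            s[i, j] = v
    return s


def _assign(scores: np.ndarray) -> dict[int, int]:
    """Maximum-weight one-to-one assignment (reference rows -> site cols)."""
    rows, cols = linear_sum_assignment(-scores)
    return dict(zip(rows.tolist(), cols.tolist()))


def _refine_mapping(
    mapping: dict[int, int], ref_ca: np.ndarray, site_ca: np.ndarray
) -> dict[int, int]:
    """Iterate Kabsch + proximity re-assignment (<= 3 A) until stable."""
    for _ in range(REFINE_ROUNDS):
        pairs = sorted(mapping.items())
        if len(pairs) < 3:
            return mapping
        ia = [p[0] for p in pairs]
        ib = [p[1] for p in pairs]
        try:
            rot, trans, _ = kabsch(site_ca[ib], ref_ca[ia])
        except ValueError:
            return mapping
        moved = site_ca @ rot.T + trans
        dev = np.linalg.norm(moved[ib] - ref_ca[ia], axis=1)
        keep = {i: j for (i, j), dv in zip(pairs, dev) if dv <= REFINE_DROP_A}
        dist = cdist(ref_ca, moved)
        cost = dist.copy()
        cost[dist > REFINE_DROP_A] = 1e6
        rows, cols = linear_sum_assignment(cost)
        new_mapping = {
            int(i): int(j) for i, j in zip(rows, cols) if dist[i, j] <= REFINE_DROP_A
        }
        if new_mapping == mapping:
            return mapping
        mapping = new_mapping if len(new_mapping) >= 3 else keep
        if len(mapping) < 3:
            return mapping
    return mapping


def _spread_triplets(dref: np.ndarray, n_anchors: int = 5) -> list[tuple[int, int, int]]:
    """All triplets of a greedy farthest-point anchor set.

    Any single anchor may be a residue with no counterpart in the other
    site (a decoy); taking every triplet of a spread anchor set guarantees
    some triplet avoids them as long as fewer than ``n_anchors - 2``
    anchors are site-specific.
    """
    import itertools

    n = len(dref)
    anchors = [0]
    while len(anchors) < min(n_anchors, n):
        dist_to_set = np.min(dref[anchors], axis=0)
        dist_to_set[anchors] = -1.0
        anchors.append(int(np.argmax(dist_to_set)))
    return list(itertools.combinations(sorted(anchors), 3))


def _triplet_seeds(
    ref_ca: np.ndarray, site_ca: np.ndarray, tol: float = 1.5, limit: int = 200
) -> list[dict[int, int]]:
    """Rigid seeds from well-spread reference triplets.

    Candidate site triplets must reproduce the reference triplet's three
    mutual distances within ``tol``; each becomes a 3-point seed mapping.
    """
    dref = cdist(ref_ca, ref_ca)
    dsite = cdist(site_ca, site_ca)
    seeds: list[dict[int, int]] = []
    n = len(site_ca)
    for a, b, c in _spread_triplets(dref):
        target = (dref[a, b], dref[a, c], dref[b, c])
        for i in range(n):
            for j in range(n):
                if j == i or abs(dsite[i, j] - target[0]) > tol:
                    continue
                for k in range(n):
                    if k in (i, j) or abs(dsite[i, k] - target[1]) > tol:
                        continue
                    if abs(dsite[j, k] - target[2]) > tol:
                        continue
                    seeds.append({a: i, b: j, c: k})
                    if len(seeds) >= limit:
                        return seeds
    return seeds


def _align_one(
    ref: ResidueShell, site: ResidueShell, scores: np.ndarray
) -> tuple[dict[int, int], np.ndarray]:
    """Match one site onto the reference; returns mapping and per-pair deviations.

    Refinement is multi-start: the descriptor/Hungarian assignment plus
    rigid triplet seeds, each refined by iterative superposition.  The final
    mapping maximizes a sequence-aware distance-kernel objective,
    sum_i [1/(1 + dev_i^2) + 0.2 * (identical letters)], which rewards many
    *tight*, identity-consistent pairs: the identity term resolves
    approximate geometric self-symmetries of a site that pure distances
    cannot; total descriptor score breaks residual ties.
    """
    ref_ca, site_ca = ref.ca_coords(), site.ca_coords()
    ref_letters = [r.letter for r in ref.residues]
    site_letters = [r.letter for r in site.residues]
    candidates = [_assign(scores)] + _triplet_seeds(ref_ca, site_ca)
    best_key, best_mapping = None, {}
    good_enough = 0.7 * min(len(ref_ca), len(site_ca))
    seen: set[tuple] = set()
    for seed in candidates:
        mapping = _refine_mapping(dict(seed), ref_ca, site_ca)
        pairs = tuple(sorted(mapping.items()))
        if len(pairs) < 3 or pairs in seen:
            continue
        seen.add(pairs)
        ia = [p[0] for p in pairs]
        ib = [p[1] for p in pairs]
        try:
            rot, trans, _ = kabsch(site_ca[ib], ref_ca[ia])
        except ValueError:
            continue
        moved = site_ca @ rot.T + trans
        dev = np.linalg.norm(moved[ib] - ref_ca[ia], axis=1)
        ident = sum(ref_letters[i] == site_letters[j] for i, j in pairs)
        key = (
            float(np.sum(1.0 / (1.0 + dev**2))) + IDENTITY_BONUS * ident,
            sum(scores[i, j] for i, j in pairs),
        )
        if best_key is None or key > best_key:
            best_key, best_mapping = key, dict(mapping)
        if best_key[0] >= good_enough:
            break
    dev_by_ref = np.full(len(ref_ca), np.nan)
    pairs = sorted(best_mapping.items())
    if len(pairs) >= 3:
        ia = [p[0] for p in pairs]
        ib = [p[1] for p in pairs]
        rot, trans, _ = kabsch(site_ca[ib], ref_ca[ia])
        moved = site_ca @ rot.T + trans
        for (i, j) in pairs:
            dev_by_ref[i] = np.linalg.norm(moved[j] - ref_ca[i])
    return best_mapping, dev_by_ref


def align_sites(shells: Sequence[ResidueShell]) -> SiteAlignment:
    """Sequence-order-independent multi-site alignment of substrate shells.

    The largest shell is the reference; every other usable site (>= 4
    residues) is matched onto it independently.  Sites smaller than 4
    residues are skipped with a warning; fewer than 2 usable sites is a
    failure.
    """
    usable = [s for s in shells if len(s) >= 4]
    for s in shells:
        if len(s) < 4:
            warnings.warn(f"{s.structure_id}: shell of {len(s)} residues skipped")
    if len(usable) < 2:
        raise ValueError("align_sites needs at least 2 shells with >= 4 residues")
    ref = max(usable, key=len)
    others = [s for s in usable if s is not ref]
    n_col = len(ref)
    matches: dict[str, list[int | None]] = {}
    shells_by_id: dict[str, ResidueShell] = {}
    score_rows = []
    dev_rows = []
    for site in others:
        scores = _pair_scores(ref, site)
        mapping, dev = _align_one(ref, site, scores)
        col_match: list[int | None] = [mapping.get(c) for c in range(n_col)]
        matches[site.structure_id] = col_match
        shells_by_id[site.structure_id] = site
        score_rows.append(
            [scores[c, mapping[c]] if c in mapping else 0.0 for c in range(n_col)]
        )
        dev_rows.append(dev)
    agreement = np.mean(np.array(score_rows), axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        deviations = np.nanmean(np.array(dev_rows), axis=0)
    return SiteAlignment(
        reference_id=ref.structure_id,
        reference_shell=ref,
        site_ids=[s.structure_id for s in others],
        matches=matches,
        agreement=agreement,
        deviations=deviations,
        shells=shells_by_id,
    )


# ---------------------------------------------------------------------------
# motif extraction


@dataclass
class Motif3D:
    """A conserved 3D residue motif: identities plus template C-alpha geometry.

    ``positions[k]`` is (consensus letter, allowed alternative letters);
    ``template_distances`` the pairwise C-alpha distances of the reference
    site restricted to the motif positions; ``template_coords`` the matching
    reference coordinates (used for the final superposition in search).
    """

    positions: list[tuple[str, frozenset[str]]]
    template_distances: np.ndarray
    template_coords: np.ndarray
    reference_keys: list[tuple[str, int, str]]
    support: int
    m_dist_min: float
    m_dist_max: float
    tol_distance_A: float = 1.5
    tol_rmsd_A: float = 2.0

    def __post_init__(self) -> None:
        k = len(self.positions)
        if k < 3:
            raise ValueError("a 3D motif needs at least 3 positions")
        if self.support < 2:
            raise ValueError("motif support must cover at least 2 sites")
        self.template_distances = np.asarray(self.template_distances, float)
        if self.template_distances.shape != (k, k):
            raise ValueError("template distance matrix shape mismatch")

    def allowed(self, k: int) -> frozenset[str]:
        letter, alts = self.positions[k]
        return frozenset({letter}) | alts

    def to_json(self, path: str | Path) -> None:
        data = {
            "positions": [
                {"consensus": c, "alternatives": sorted(a)} for c, a in self.positions
            ],
            "template_distances": self.template_distances.tolist(),
            "template_coords": self.template_coords.tolist(),
            "reference_keys": [list(k) for k in self.reference_keys],
            "support": self.support,
            "m_dist_min": self.m_dist_min,
            "m_dist_max": self.m_dist_max,
            "tol_distance_A": self.tol_distance_A,
            "tol_rmsd_A": self.tol_rmsd_A,
        }
        Path(path).write_text(json.dumps(data, indent=2), encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "Motif3D":
        data = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            positions=[
                (p["consensus"], frozenset(p["alternatives"])) for p in data["positions"]
            ],
            template_distances=np.array(data["template_distances"]),
            template_coords=np.array(data["template_coords"]),
            reference_keys=[tuple(k) for k in data["reference_keys"]],
            support=data["support"],
            m_dist_min=data["m_dist_min"],
            m_dist_max=data["m_dist_max"],
            tol_distance_A=data["tol_distance_A"],
            tol_rmsd_A=data["tol_rmsd_A"],
        )


def extract_motif(
    alignment: SiteAlignment,
    m_dist_min: float = 0.6,
    m_dist_max: float = 0.4,
    alternative_fraction: float = 0.2,
) -> Motif3D:
    """Extract the representative 3D motif from a multi-site alignment.

    Per column, coverage c = fraction of sites with a matched residue and
    geometric tightness g = 1 - mean C-alpha deviation / 3 A (floored at 0).
    Columns pass with c > ``m_dist_min`` and g > ``m_dist_max``.  The
    consensus letter is the modal residue; alternatives are letters seen in
    at least ``alternative_fraction`` of sites.  Template geometry is the
    across-site consensus: each site is superposed onto the reference and
    the matched C-alpha coordinates are averaged per column, which damps
    the single-site coordinate noise a raw reference template would carry.
    """
    n_sites = len(alignment.site_ids)
    retained: list[int] = []
    for c in range(alignment.n_columns):
        matched = sum(
            1 for sid in alignment.site_ids if alignment.matches[sid][c] is not None
        )
        cov = matched / n_sites
        dev = alignment.deviations[c]
        tight = max(0.0, 1.0 - (dev / REFINE_DROP_A)) if np.isfinite(dev) else 0.0
        if cov > m_dist_min and tight > m_dist_max:
            retained.append(c)
    if len(retained) < 3:
        raise ValueError("no representative motif: fewer than 3 columns retained")
    positions = []
    for c in retained:
        letters = alignment.column_letters(c)
        counts = pd.Series(letters).value_counts()
        consensus = counts.index[0]
        alts = frozenset(
            l for l, n in counts.items() if n / len(letters) >= alternative_fraction and l != consensus
        )
        positions.append((consensus, alts))
    # consensus template coordinates: mean over reference + superposed sites
    ref_ca_all = alignment.reference_shell.ca_coords()
    sums = {c: [ref_ca_all[c]] for c in retained}
    for sid in alignment.site_ids:
        site_ca = alignment.shells[sid].ca_coords()
        pairs = [
            (c, m)
            for c, m in enumerate(alignment.matches[sid])
            if m is not None
        ]
        if len(pairs) < 3:
            continue
        ia = [p[0] for p in pairs]
        ib = [p[1] for p in pairs]
        try:
            rot, trans, _ = kabsch(site_ca[ib], ref_ca_all[ia])
        except ValueError:
            continue
        moved = site_ca @ rot.T + trans
        for c, m in pairs:
            if c in sums:
                sums[c].append(moved[m])
    mean_ca = np.array([np.mean(sums[c], axis=0) for c in retained])
    return Motif3D(
        positions=positions,
        template_distances=cdist(mean_ca, mean_ca),
        template_coords=mean_ca,
        reference_keys=[alignment.columns[c] for c in retained],
        support=n_sites + 1,
        m_dist_min=m_dist_min,
        m_dist_max=m_dist_max,
    )


def conservation_profile(alignment: SiteAlignment) -> pd.DataFrame:
    """Per-column residue frequencies (and gap fraction) of a site alignment.

    Rows are columns of the alignment; letter frequencies are over non-gap
    matches (reference included) and sum to 1; the ``gap`` column reports
    the fraction of sites without a match.
    """
    rows = []
    n_sites = len(alignment.site_ids)
    for c in range(alignment.n_columns):
        letters = alignment.column_letters(c)
        freqs = pd.Series(letters).value_counts(normalize=True).to_dict()
        gaps = sum(
            1 for sid in alignment.site_ids if alignment.matches[sid][c] is None
        )
        rows.append({"column": c, "gap": gaps / n_sites, **freqs})
    return pd.DataFrame(rows).fillna(0.0).set_index("column")


# ---------------------------------------------------------------------------
# motif search


@dataclass(frozen=True)
class MotifMatch:
    """One placement of a motif in a query structure."""

    structure_id: str
    residue_keys: tuple[tuple[str, int, str], ...]
    rmsd_A: float
    mismatches: int


def _query_residues(query: StructureModel | ResidueShell):
    residues = [r for r in query.residues if r.ca is not None]
    coords = np.array([r.ca for r in residues])
    return residues, coords


def search_motif(
    motif: Motif3D,
    query: StructureModel | ResidueShell,
    policy: str = "strict",
) -> list[MotifMatch]:
    """Find motif placements in a query structure.

    Candidate residue tuples are enumerated by residue identity (strict: the
    letter must be consensus-or-alternative at every position; relaxed: at
    most one position may violate), pruned by pairwise C-alpha distance
    compatibility with the template (each pair within ``tol_distance_A``),
    and finally superposed onto the template; matches with RMSD <=
    ``tol_rmsd_A`` are returned sorted by (mismatches, rmsd).
    """
    if policy not in {"strict", "relaxed"}:
        raise ValueError(f"unknown policy {policy!r}")
    budget = 0 if policy == "strict" else 1
    residues, coords = _query_residues(query)
    k = len(motif.positions)
    if k > len(residues):
        return []
    dmat = cdist(coords, coords)
    letters = [r.letter for r in residues]
    allowed = [motif.allowed(p) for p in range(k)]
    tmpl = motif.template_distances
    tol = motif.tol_distance_A
    matches: list[MotifMatch] = []

    def extend(assigned: list[int], mismatches: int) -> None:
        pos = len(assigned)
        if pos == k:
            sel = np.array(assigned)
            try:
                _, _, rmsd = kabsch(coords[sel], motif.template_coords)
            except ValueError:
                return
            if rmsd <= motif.tol_rmsd_A:
                matches.append(
                    MotifMatch(
                        structure_id=query.structure_id,
                        residue_keys=tuple(residues[i].key for i in assigned),
                        rmsd_A=rmsd,
                        mismatches=mismatches,
                    )
                )
            return
        for idx in range(len(residues)):
            if idx in assigned:
                continue
            miss = 0 if letters[idx] in allowed[pos] else 1
            if mismatches + miss > budget:
                continue
            ok = all(
                abs(dmat[idx, assigned[q]] - tmpl[pos, q]) <= tol for q in range(pos)
            )
            if ok:
                extend(assigned + [idx], mismatches + miss)

    extend([], 0)
    return sorted(matches, key=lambda m: (m.mismatches, m.rmsd_A))


def match_table(matches: Iterable[MotifMatch]) -> pd.DataFrame:
    """Motif matches as a tidy report table."""
    rows = [
        {
            "structure_id": m.structure_id,
            "residues": ";".join(f"{c}{n}:{r}" for c, n, r in m.residue_keys),
            "rmsd_A": m.rmsd_A,
            "mismatches": m.mismatches,
        }
        for m in matches
    ]
    return pd.DataFrame(rows, columns=["structure_id", "residues", "rmsd_A", "mismatches"])
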