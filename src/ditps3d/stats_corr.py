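"""Composition statistics, residue preferences, correlations, group tests.

The quantitative core of the analysis: amino-acid composition (AAC) and
grouped composition (GAAC) of substrate shells versus whole sequences,
per-residue preferential values (shell frequency / overall frequency),
Pearson cross-correlations between the pairwise similarity factors
(sequence regions, TM-scores, product Dice), and Mann-Whitney same-vs-
different group comparisons that back the box-plot style summaries.

The pair universe for every correlation is the set of unordered distinct
enzyme pairs present in all factors, diagonal excluded, with listwise
deletion of pairs missing in any factor.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_model import EnzymeRecord
from .seq_analysis import SimilarityMatrix

__all__ = [
    "AA_ORDER",
    "GAAC_GROUPS",
    "CompositionVector",
    "PreferenceVector",
    "composition",
    "preference",
    "condense",
    "pearson",
    "CorrelationReport",
    "correlation_report",
    "group_compare",
    "pair_partition",
    "pair_values",
]

AA_ORDER = tuple("ACDEFGHIKLMNPQRSTVWY")
#: Five physicochemical groups partitioning the 20 standard letters.
GAAC_GROUPS: dict[str, frozenset[str]] = {
    "aliphatic": frozenset("GAVLMI"),
    "aromatic": frozenset("FYW"),
    "positive": frozenset("KRH"),
    "negative": frozenset("DE"),
    "uncharged": frozenset("STCPNQ"),
}


@dataclass
class CompositionVector:
    """AAC (20-vector) and GAAC (5-vector) frequencies of a residue string."""

    aac: dict[str, float]
    gaac: dict[str, float]
    n_counted: int
    n_skipped_x: int = 0

    @property
    def empty(self) -> bool:
        return self.n_counted == 0


def composition(letters: str) -> CompositionVector:
    """Amino-acid and grouped composition of a sequence or shell string.

    X residues are skipped (their count is noted); frequencies are over the
    counted letters and sum to 1, or are all-zero with the empty flag set.
    """
    counted = [c for c in letters.upper() if c in AA_ORDER]
    skipped = sum(1 for c in letters.upper() if c == "X")
    n = len(counted)
    if n == 0:
        return CompositionVector(
            aac={a: 0.0 for a in AA_ORDER},
            gaac={g: 0.0 for g in GAAC_GROUPS},
            n_counted=0,
            n_skipped_x=skipped,
        )
    counts = pd.Series(counted).value_counts()
    aac = {a: float(counts.get(a, 0)) / n for a in AA_ORDER}
    gaac = {
        g: sum(aac[a] for a in AA_ORDER if a in members)
        for g, members in GAAC_GROUPS.items()
    }
    return CompositionVector(aac=aac, gaac=gaac, n_counted=n, n_skipped_x=skipped)


@dataclass
class PreferenceVector:
    """Per-letter shell/overall frequency ratios; undefined where overall = 0."""

    ratio: dict[str, float]
    undefined: frozenset[str]


def preference(shell_letters: str, full_sequence: str) -> PreferenceVector:
    """Residue preferential value: shell frequency / full-sequence frequency.

    Letters absent from the full sequence are flagged undefined rather than
    divided; an empty shell yields all-zero ratios (a valid result).
    """
    if not full_sequence:
        raise ValueError("full sequence must be non-empty")
    shell = composition(shell_letters)
    full = composition(full_sequence)
    ratio: dict[str, float] = {}
    undefined: set[str] = set()
    for a in AA_ORDER:
        if full.aac[a] == 0.0:
            if shell.aac[a] > 0.0:
                undefined.add(a)
            ratio[a] = 0.0
        else:
            ratio[a] = shell.aac[a] / full.aac[a]
    return PreferenceVector(ratio=ratio, undefined=frozenset(undefined))


# ---------------------------------------------------------------------------
# correlations


def condense(
    matrix: SimilarityMatrix, id_subset: Sequence[str] | None = None
) -> tuple[np.ndarray, list[tuple[str, str]]]:
    """Upper-triangle values of a similarity matrix in fixed pair order.

    Pairs are (i, j) with i < j in the order of ``id_subset`` (default: the
    matrix's own id order).  Returns the value vector (NaN for missing) and
    the matching pair labels.
    """
    ids = list(id_subset) if id_subset is not None else list(matrix.ids)
    missing = [a for a in ids if a not in matrix.ids]
    if missing:
        raise ValueError(f"ids not in matrix: {missing}")
    pos = {a: matrix.ids.index(a) for a in ids}
    pairs = list(itertools.combinations(ids, 2))
    vals = np.array([matrix.values[pos[a], pos[b]] for a, b in pairs])
    return vals, pairs


def pearson(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, int]:
    """Pearson product-moment correlation with a two-sided t-test p-value.

    Computed from the closed form; p from t = r sqrt((n-2)/(1-r^2)) on
    n - 2 degrees of freedom.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y):
        raise ValueError("vectors differ in length")
    n = len(x)
    if n < 3:
        raise ValueError("pearson needs n >= 3")
    xm, ym = x - x.mean(), y - y.mean()
    sx = math.sqrt(float(xm @ xm))
    sy = math.sqrt(float(ym @ ym))
    if sx == 0.0 or sy == 0.0:
        raise ValueError("degenerate factor: zero variance")
    r = float(xm @ ym) / (sx * sy)
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * math.sqrt((n - 2) / (1.0 - r * r))
        p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return r, p, n


@dataclass
class CorrelationReport:
    """Pearson cross-correlations between similarity factors."""

    entries: list[dict]  # factor_a, factor_b, r, p, n

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["factor_a", "factor_b", "r", "p", "n"])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def get(self, factor_a: str, factor_b: str) -> dict:
        for e in self.entries:
            if {e["factor_a"], e["factor_b"]} == {factor_a, factor_b}:
                return e
        raise KeyError(f"no entry for ({factor_a}, {factor_b})")


def correlation_report(
    factors: Mapping[str, SimilarityMatrix],
    benjamini_hochberg: bool = False,
) -> CorrelationReport:
    """Pearson r for every factor pair over the intersected pair universe.

    All factors are condensed over the shared enzyme ids; pairs with a
    missing value in any factor are dropped listwise so every entry uses
    the same pair universe.  Optionally adds Benjamini-Hochberg adjusted
    p-values (off by default, mirroring an unadjusted correlation table).
    """
    if len(factors) < 2:
        raise ValueError("need at least 2 factors")
    kinds = list(factors)
    shared = [a for a in factors[kinds[0]].ids if all(a in factors[k].ids for k in kinds)]
    if len(shared) < 3:
        raise ValueError("fewer than 3 shared enzymes across factors")
    condensed = {}
    for k in kinds:
        vals, _ = condense(factors[k], shared)
        condensed[k] = vals
    mat = np.vstack([condensed[k] for k in kinds])
    keep = ~np.isnan(mat).any(axis=0)
    if keep.sum() < 3:
        raise ValueError("fewer than 3 complete pairs across factors")
    entries = []
    for a, b in itertools.combinations(kinds, 2):
        try:
            r, p, n = pearson(condensed[a][keep], condensed[b][keep])
        except ValueError as exc:
            raise ValueError(f"correlation failed for ({a}, {b}): {exc}") from exc
        entries.append({"factor_a": a, "factor_b": b, "r": r, "p": p, "n": n})
    if benjamini_hochberg and entries:
        ps = np.array([e["p"] for e in entries])
        order = np.argsort(ps)
        m = len(ps)
        adj = np.empty(m)
        running = 1.0
        for rank_idx in range(m - 1, -1, -1):
            i = order[rank_idx]
            running = min(running, ps[i] * m / (rank_idx + 1))
            adj[i] = running
        for e, q in zip(entries, adj):
            e["p_adjusted"] = float(q)
    return CorrelationReport(entries=entries)


# ---------------------------------------------------------------------------
# group comparisons


def group_compare(
    values_same: Sequence[float], values_different: Sequence[float]
) -> dict:
    """Two-sided Mann-Whitney U comparison of two similarity-value groups.

    Uses the exact U distribution when the combined sample is small
    (n <= 20) and there are no ties, the tie-corrected normal approximation
    otherwise.  Also returns five-number summaries of both groups.
    """
    xs = np.asarray(values_same, float)
    ys = np.asarray(values_different, float)
    if len(xs) < 3 or len(ys) < 3:
        raise ValueError("each group needs at least 3 values")
    has_ties = len(np.unique(np.concatenate([xs, ys]))) < len(xs) + len(ys)
    method = "exact" if (len(xs) + len(ys) <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(xs, ys, alternative="two-sided", method=method)

    def summary(v: np.ndarray) -> dict:
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        return {
            "min": float(v.min()),
            "q1": float(q1),
            "median": float(med),
            "q3": float(q3),
            "max": float(v.max()),
        }

    return {
        "U": float(res.statistic),
        "p": float(res.pvalue),
        "method": method,
        "n_same": len(xs),
        "n_different": len(ys),
        "same": summary(xs),
        "different": summary(ys),
    }


def _key_sets(record: EnzymeRecord, key: str) -> set[str]:
    if key == "substrate":
        return {record.substrate} if record.substrate else set()
    if key == "product_skeleton":
        return {s for s in record.skeleton_labels if s != "unassigned"}
    raise ValueError(f"unknown partition key {key!r}")


def pair_partition(
    records: Sequence[EnzymeRecord], key: str = "substrate"
) -> tuple[list[tuple[str, str]], list[tuple[str, str]]]:
    """Split unordered enzyme pairs into same / different groups by a key.

    A pair is "same" when the two enzymes' key sets intersect (any shared
    substrate, or any shared skeleton label).  Records with an empty key
    set are excluded with a warning.
    """
    keyed = []
    for r in records:
        ks = _key_sets(r, key)
        if not ks:
            warnings.warn(f"{r.accession}: no {key} annotation; excluded from partition")
            continue
        keyed.append((r.accession, ks))
    same, different = [], []
    for (acc_a, ka), (acc_b, kb) in itertools.combinations(keyed, 2):
        (same if ka & kb else different).append((acc_a, acc_b))
    return same, different


def pair_values(
    matrix: SimilarityMatrix, pairs: Iterable[tuple[str, str]]
) -> np.ndarray:
    """Matrix values for a list of unordered pairs, dropping missing entries."""
    out = []
    for a, b in pairs:
        if a in matrix.ids and b in matrix.ids:
            v = matrix.get(a, b)
            if not np.isnan(v):
                out.append(v)
    return np.array(out)
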