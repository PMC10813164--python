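"""Sequence-level analysis: signature motifs, classes, domains, identity, SSN.

Terpene synthases carry short aspartate-rich signature motifs that pin down
the mechanistic class: DDXXD and the NSE/DTE triad mark the class I
(ionization) active site in the C-terminal alpha domain, DXDD marks the
class II (protonation) site at the beta-gamma interface, and LHS / PNV /
PIX / FEHXW / FERLW are accessory motifs characteristic of copalyl
diphosphate synthases and relatives.  This module scans those patterns,
assigns classes from them, splits sequences into N-/C-terminal domains,
computes pairwise percent identity under a global BLOSUM62 alignment, and
builds sequence similarity networks (SSNs) by thresholding the resulting
matrices.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .io_model import ClassLabel, EnzymeRecord

__all__ = [
    "MOTIF_PATTERNS",
    "MotifHit",
    "SimilarityMatrix",
    "scan_signature_motifs",
    "classify_class",
    "split_domains",
    "pairwise_identity",
    "similarity_matrix",
    "build_ssn",
    "evalue_from_score",
    "write_ssn",
]

#: Signature motif patterns.  X means any residue; NSE/DTE is a permissive
#: triad spanning both spellings of the class I metal-binding motif.
MOTIF_PATTERNS: dict[str, str] = {
    "DDXXD": r"DD..D",
    "DXDD": r"D.DD",
    "NSE_DTE": r"[ND]D..[ST].[ED]",
    "LHS": r"LHS",
    "PNV": r"PNV",
    "PIX": r"PI.",
    "FEHXW": r"FEH.W",
    "FERLW": r"FERLW",
}

#: Motifs anchoring the class II (beta-gamma, N-terminal) active site and the
#: class I (alpha, C-terminal) active site, used for the anchor-based domain
#: split.
CLASS_II_ANCHORS = ("DXDD", "LHS")
CLASS_I_ANCHORS = ("DDXXD", "NSE_DTE")


@dataclass(frozen=True)
class MotifHit:
    """One signature-motif occurrence (1-based start)."""

    motif_name: str
    start: int
    matched_text: str

    @property
    def end(self) -> int:
        """1-based inclusive end position."""
        return self.start + len(self.matched_text) - 1


def scan_signature_motifs(sequence: str, motifs: Iterable[str] | None = None) -> list[MotifHit]:
    """Find all non-overlapping occurrences of each signature motif.

    Matches of different motifs may overlap each other; within one motif the
    scan is the usual left-to-right non-overlapping sweep.  Hits are sorted
    by start position, then motif name.
    """
    seq = sequence.upper()
    hits: list[MotifHit] = []
    for name in motifs or MOTIF_PATTERNS:
        pat = MOTIF_PATTERNS[name]
        for m in re.finditer(pat, seq):
            hits.append(MotifHit(name, m.start() + 1, m.group()))
    return sorted(hits, key=lambda h: (h.start, h.motif_name))


def classify_class(sequence: str) -> ClassLabel:
    """Assign the mechanistic class from the signature motifs.

    DDXXD or NSE/DTE present and DXDD absent -> class I; DXDD present and
    DDXXD absent -> class II; both kinds present -> bifunctional I/II;
    neither -> unknown.
    """
    hits = {h.motif_name for h in scan_signature_motifs(sequence, ("DDXXD", "NSE_DTE", "DXDD"))}
    has_i = bool(hits & {"DDXXD", "NSE_DTE"})
    has_ii = "DXDD" in hits
    if has_i and has_ii:
        return ClassLabel.I_II
    if has_i:
        return ClassLabel.I
    if has_ii:
        return ClassLabel.II
    return ClassLabel.UNKNOWN


def split_domains(record: EnzymeRecord) -> dict[str, str]:
    """Slice the sequence into N- and C-terminal domain subsequences.

    Provided ``domain_ranges`` take precedence.  Otherwise the boundary is
    the (half-up rounded) midpoint between the end of the last class II
    anchor hit (DXDD / LHS, beta-gamma region) and the start of the first
    class I anchor hit (DDXXD / NSE-DTE, alpha domain): N = [1, boundary],
    C = (boundary, len].
    """
    seq = record.sequence
    if record.domain_ranges:
        out = {}
        for dom in ("N", "C"):
            if dom in record.domain_ranges:
                a, b = record.domain_ranges[dom]
                out[dom] = seq[a - 1 : b]
        if out:
            return out
    hits = scan_signature_motifs(seq)
    ii_hits = [h for h in hits if h.motif_name in CLASS_II_ANCHORS]
    i_hits = [h for h in hits if h.motif_name in CLASS_I_ANCHORS]
    if not ii_hits or not i_hits:
        raise ValueError(f"{record.accession}: cannot split — missing domain ranges and anchors")
    last_ii_end = max(h.end for h in ii_hits)
    first_i_start = min(h.start for h in i_hits)
    if first_i_start <= last_ii_end:
        raise ValueError(f"{record.accession}: cannot split — anchors overlap")
    boundary = (last_ii_end + first_i_start + 1) // 2
    return {"N": seq[:boundary], "C": seq[boundary:]}


# ---------------------------------------------------------------------------
# pairwise identity

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = _BLOSUM62
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    aligner.mode = "global"
    return aligner


_ALIGNER = _make_aligner()


def pairwise_identity(seq_a: str, seq_b: str, return_alignment: bool = False):
    """Percent identity under a global BLOSUM62 alignment (affine 10/0.5).

    Identity = 100 x identical aligned columns / alignment length, where the
    length counts internal gap columns but excludes terminal-gap overhangs
    (so N/C domain slices of different lengths are not penalised for the
    overhang their construction guarantees).
    """
    if not seq_a or not seq_b:
        raise ValueError("pairwise_identity requires two non-empty sequences")
    a, b = seq_a.upper(), seq_b.upper()
    aln = _ALIGNER.align(a, b)[0]
    ra, rb = aln[0], aln[1]
    # trim terminal-gap columns: first/last column where both rows have residues
    first = 0
    while ra[first] == "-" or rb[first] == "-":
        first += 1
    last = len(ra) - 1
    while ra[last] == "-" or rb[last] == "-":
        last -= 1
    ident = sum(1 for x, y in zip(ra[first : last + 1], rb[first : last + 1]) if x == y)
    length = last - first + 1
    pid = 100.0 * ident / length
    if return_alignment:
        return pid, aln
    return pid


def alignment_score(seq_a: str, seq_b: str) -> float:
    """Raw global alignment score (BLOSUM62, affine 10/0.5)."""
    return float(_ALIGNER.score(seq_a.upper(), seq_b.upper()))


# ---------------------------------------------------------------------------
# similarity matrices


@dataclass
class SimilarityMatrix:
    """Symmetric pairwise similarity matrix over an ordered set of enzymes.

    ``scale`` declares the value range: "percent" for identities in
    [0, 100] and "unit" for scores in [0, 1].  Missing comparisons are NaN.
    """

    ids: list[str]
    values: np.ndarray
    kind: str
    scale: str = "unit"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError(f"matrix shape {self.values.shape} does not match {n} ids")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValueError("similarity matrix must be symmetric")

    @property
    def max_scale(self) -> float:
        return 100.0 if self.scale == "percent" else 1.0

    def get(self, a: str, b: str) -> float:
        i, j = self.ids.index(a), self.ids.index(b)
        return float(self.values[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path, kind: str, scale: str = "unit") -> "SimilarityMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(ids=[str(i) for i in df.index], values=df.values, kind=kind, scale=scale)


def _region_slices(records: Sequence[EnzymeRecord], region: str) -> list[str]:
    if region == "full":
        return [r.sequence for r in records]
    failed, out = [], []
    for r in records:
        try:
            doms = split_domains(r)
        except ValueError:
            failed.append(r.accession)
            continue
        if region == "NC":
            out.append(doms.get("N", "") + doms.get("C", ""))
        else:
            out.append(doms.get(region, ""))
    if failed:
        raise ValueError(f"cannot split domains for: {failed}")
    return out


def similarity_matrix(records: Sequence[EnzymeRecord], region: str = "full") -> SimilarityMatrix:
    """All-vs-all percent identity over a sequence region (N, C, NC, or full)."""
    if region not in {"N", "C", "NC", "full"}:
        raise ValueError(f"unknown region {region!r}")
    seqs = _region_slices(records, region)
    n = len(records)
    vals = np.full((n, n), np.nan)
    for i in range(n):
        vals[i, i] = 100.0 if seqs[i] else np.nan
        for j in range(i + 1, n):
            if seqs[i] and seqs[j]:
                vals[i, j] = vals[j, i] = pairwise_identity(seqs[i], seqs[j])
    return SimilarityMatrix(
        ids=[r.accession for r in records],
        values=vals,
        kind=f"seq_{region}" if region != "full" else "seq_full",
        scale="percent",
    )


# ---------------------------------------------------------------------------
# sequence similarity network

# Karlin-Altschul constants for gapped BLOSUM62 (open 10 / extend 0.5 regime)
KA_LAMBDA = 0.267
KA_K = 0.041


def evalue_from_score(score: float, len_a: int, len_b: int) -> float:
    """Karlin-Altschul E-value for a raw gapped BLOSUM62 alignment score."""
    return KA_K * len_a * len_b * math.exp(-KA_LAMBDA * score)


def build_ssn(
    matrix: SimilarityMatrix,
    threshold: float,
    node_attrs: Mapping[str, Mapping] | None = None,
    mode: str = "identity",
) -> nx.Graph:
    """Build a sequence similarity network by thresholding a pairwise matrix.

    In "identity" mode an edge (a, b) exists iff similarity >= threshold
    (threshold on the matrix scale); in "evalue" mode the matrix must hold
    E-values and edges satisfy value <= threshold.  Isolated nodes are
    retained; there are no self-edges.
    """
    if mode == "identity" and not (0 <= threshold <= matrix.max_scale):
        raise ValueError(f"threshold {threshold} outside [0, {matrix.max_scale}]")
    if mode == "evalue" and threshold <= 0:
        raise ValueError("E-value threshold must be positive")
    g = nx.Graph(threshold=threshold, kind=matrix.kind, mode=mode)
    for i, acc in enumerate(matrix.ids):
        attrs = dict(node_attrs.get(acc, {})) if node_attrs else {}
        g.add_node(acc, **attrs)
    n = len(matrix.ids)
    for i in range(n):
        for j in range(i + 1, n):
            v = matrix.values[i, j]
            if np.isnan(v):
                continue
            keep = v >= threshold if mode == "identity" else v <= threshold
            if keep:
                g.add_edge(matrix.ids[i], matrix.ids[j], score=float(v))
    return g


def write_ssn(graph: nx.Graph, edge_tsv: str | Path, graphml: str | Path | None = None) -> None:
    """Export an SSN as an edge-list TSV and optionally GraphML."""
    rows = [
        {"source": a, "target": b, "score": d.get("score", float("nan"))}
        for a, b, d in graph.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["source", "target", "score"]).to_csv(
        edge_tsv, sep="\t", index=False
    )
    if graphml is not None:
        nx.write_graphml(graph, graphml)


def motif_hits_table(records: Sequence[EnzymeRecord]) -> pd.DataFrame:
    """Motif hits for a cohort as a tidy table (accession, motif, start, text)."""
    rows = []
    for r in records:
        for h in scan_signature_motifs(r.sequence):
            rows.append(
                {"accession": r.accession, "motif": h.motif_name, "start": h.start, "text": h.matched_text}
            )
    return pd.DataFrame(rows, columns=["accession", "motif", "start", "text"])
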