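import itertools

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from ditps3d.io_model import ClassLabel, EnzymeRecord
from ditps3d.seq_analysis import (
    build_ssn,
    classify_class,
    pairwise_identity,
    scan_signature_motifs,
    similarity_matrix,
    split_domains,
    SimilarityMatrix,
)

# ---------------------------------------------------------------------------
# motif scanning


class TestMotifScan:
    @pytest.mark.parametrize(
        "seq,motif,start,text",
        [
            ("AADDYYDAA", "DDXXD", 3, "DDYYD"),
            ("MDIDDA", "DXDD", 2, "DIDD"),
            ("AFEHLWA", "FEHXW", 2, "FEHLW"),
            ("AFERLWA", "FERLW", 2, "FERLW"),
            ("XXLHSXX", "LHS", 3, "LHS"),
            ("ANDAASAEA", "NSE_DTE", 2, "NDAASAE"),
        ],
    )
    def test_single_hits(self, seq, motif, start, text):
        hits = [h for h in scan_signature_motifs(seq) if h.motif_name == motif]
        assert len(hits) == 1
        assert hits[0].start == start and hits[0].matched_text == text

    def test_absent_motif_gives_no_hit(self):
        assert not [h for h in scan_signature_motifs("AAAAAA") if h.motif_name == "PNV"]

    def test_matched_text_equals_slice(self):
        seq = "MDIDDAADDYYDAALHSA"
        for h in scan_signature_motifs(seq):
            assert seq[h.start - 1 : h.start - 1 + len(h.matched_text)] == h.matched_text

    def test_hits_sorted_by_start(self):
        starts = [h.start for h in scan_signature_motifs("MDIDDAADDYYDAALHSA")]
        assert starts == sorted(starts)

    def test_empty_sequence(self):
        assert scan_signature_motifs("") == []


class TestClassify:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("AAADDYYDAAA", ClassLabel.I),
            ("AAADIDDAAA", ClassLabel.II),
            ("AAADIDDAAAADDYYDAAA", ClassLabel.I_II),
            ("AAAAAAAA", ClassLabel.UNKNOWN),
        ],
    )
    def test_rules(self, seq, expected):
        assert classify_class(seq) is expected

    def test_nse_dte_counts_as_class_i(self):
        assert classify_class("AAANDAASAEAAA") is ClassLabel.I

    def test_planted_labels_recovered(self, cohort):
        for rec in cohort.records:
            assert classify_class(rec.sequence) is rec.class_label


# ---------------------------------------------------------------------------
# domain splitting


class TestSplitDomains:
    def test_explicit_ranges_take_precedence(self):
        seq = "A" * 480
        rec = EnzymeRecord(
            accession="x", sequence=seq, domain_ranges={"N": (1, 200), "C": (201, 480)}
        )
        doms = split_domains(rec)
        assert doms["N"] == seq[:200] and doms["C"] == seq[200:]

    def test_anchor_midpoint(self):
        # DXDD spelled DIDD at 50..53, DDXXD spelled DDYYD at 150..154;
        # boundary = round-half-up midpoint of (53, 150) = 102
        seq = "A" * 49 + "DIDD" + "A" * 96 + "DDYYD" + "A" * 145
        assert seq[49:53] == "DIDD" and seq[149:154] == "DDYYD"
        rec = EnzymeRecord(accession="x", sequence=seq)
        doms = split_domains(rec)
        assert len(doms["N"]) == 102
        assert doms["N"] + doms["C"] == seq

    def test_no_anchors_no_ranges_fails(self):
        rec = EnzymeRecord(accession="x", sequence="A" * 50)
        with pytest.raises(ValueError, match="cannot split"):
            split_domains(rec)


# ---------------------------------------------------------------------------
# pairwise identity, with an independent naive Gotoh oracle

_B62 = substitution_matrices.load("BLOSUM62")
OPEN, EXT = -10.0, -0.5
NEG = float("-inf")


def _gotoh(a, b):
    """Naive three-state affine DP; returns (score, matrices) for traceback."""
    n, m = len(a), len(b)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = OPEN + (i - 1) * EXT
    for j in range(1, m + 1):
        Y[0][j] = OPEN + (j - 1) * EXT
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = _B62[a[i - 1], b[j - 1]]
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] + OPEN, Y[i - 1][j] + OPEN, X[i - 1][j] + EXT)
            Y[i][j] = max(M[i][j - 1] + OPEN, X[i][j - 1] + OPEN, Y[i][j - 1] + EXT)
    return max(M[n][m], X[n][m], Y[n][m]), (M, X, Y)


def _optimal_identities(a, b, cap=400):
    """Identity values (terminal gaps excluded) of every optimal alignment."""
    score, (M, X, Y) = _gotoh(a, b)
    results = set()
    stack = []
    n, m = len(a), len(b)
    for st, v in (("M", M[n][m]), ("X", X[n][m]), ("Y", Y[n][m])):
        if v == score:
            stack.append((n, m, st, []))
    while stack and len(results) < cap:
        i, j, st, cols = stack.pop()
        if i == 0 and j == 0:
            cols = cols[::-1]
            first = 0
            while cols[first][0] is None or cols[first][1] is None:
                first += 1
            last = len(cols) - 1
            while cols[last][0] is None or cols[last][1] is None:
                last -= 1
            window = cols[first : last + 1]
            ident = sum(1 for x, y in window if x == y and x is not None)
            results.add(round(100.0 * ident / len(window), 9))
            continue
        if st == "M":
            s = _B62[a[i - 1], b[j - 1]]
            tgt = M[i][j] - s
            for prev, v in (("M", M[i - 1][j - 1]), ("X", X[i - 1][j - 1]), ("Y", Y[i - 1][j - 1])):
                if abs(v - tgt) < 1e-9:
                    stack.append((i - 1, j - 1, prev, cols + [(a[i - 1], b[j - 1])]))
        elif st == "X":
            for prev, v in (("M", M[i - 1][j] + OPEN), ("Y", Y[i - 1][j] + OPEN), ("X", X[i - 1][j] + EXT)):
                if abs(v - X[i][j]) < 1e-9:
                    stack.append((i - 1, j, prev, cols + [(a[i - 1], None)]))
        else:
            for prev, v in (("M", M[i][j - 1] + OPEN), ("X", X[i][j - 1] + OPEN), ("Y", Y[i][j - 1] + EXT)):
                if abs(v - Y[i][j]) < 1e-9:
                    stack.append((i, j - 1, prev, cols + [(None, b[j - 1])]))
    return score, results


class TestPairwiseIdentity:
    def test_identical_sequences(self):
        assert pairwise_identity("MKLVW", "MKLVW") == 100.0

    def test_three_quarters(self):
        assert pairwise_identity("AAAA", "AATA") == pytest.approx(75.0)

    def test_symmetry(self):
        a, b = "MKLVWYFRH", "MKLWYFH"
        assert pairwise_identity(a, b) == pytest.approx(pairwise_identity(b, a))

    def test_hundred_iff_equal(self):
        assert pairwise_identity("mklvw", "MKLVW") == 100.0
        assert pairwise_identity("MKLVW", "MKLVY") < 100.0

    def test_dissimilar_sequences_score_low(self):
        rng = np.random.default_rng(0)
        a = "".join(rng.choice(list("ILVFM"), size=20))
        b = "".join(rng.choice(list("DEKRH"), size=20))
        assert pairwise_identity(a, b) < 30.0

    def test_empty_input_fails(self):
        with pytest.raises(ValueError):
            pairwise_identity("", "MKL")

    def test_matches_naive_gotoh_oracle(self):
        from ditps3d.seq_analysis import alignment_score

        rng = np.random.default_rng(42)
        aa = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(20):
            la, lb = rng.integers(3, 13, size=2)
            a = "".join(rng.choice(aa, size=la))
            b = "".join(rng.choice(aa, size=lb))
            oracle_score, idents = _optimal_identities(a, b)
            assert alignment_score(a, b) == pytest.approx(oracle_score, abs=1e-9)
            pid = pairwise_identity(a, b)
            assert any(abs(pid - v) < 1e-6 for v in idents), (a, b, pid, idents)


# ---------------------------------------------------------------------------
# similarity matrices and the SSN


def _rec(acc, seq, ranges=None):
    return EnzymeRecord(accession=acc, sequence=seq, domain_ranges=ranges)


class TestSimilarityMatrix:
    def test_identical_records(self):
        recs = [_rec("a", "MKLVWYF"), _rec("b", "MKLVWYF")]
        mat = similarity_matrix(recs, "full")
        assert np.allclose(mat.values, 100.0)

    def test_symmetric_random_cohort(self, cohort):
        mat = similarity_matrix(cohort.records[:5], "full")
        assert np.allclose(mat.values, mat.values.T)
        assert np.allclose(np.diag(mat.values), 100.0)

    def test_region_slicing_uses_ranges(self):
        seq = "MKLVW" + "YFRHG"
        recs = [
            _rec("a", seq, {"N": (1, 5), "C": (6, 10)}),
            _rec("b", seq, {"N": (1, 5), "C": (6, 10)}),
        ]
        n = similarity_matrix(recs, "N")
        nc = similarity_matrix(recs, "NC")
        assert np.allclose(n.values, 100.0) and np.allclose(nc.values, 100.0)

    def test_unsplittable_record_fails_with_accessions(self):
        recs = [_rec("good", "A" * 20, {"N": (1, 10), "C": (11, 20)}), _rec("bad", "A" * 20)]
        with pytest.raises(ValueError, match="bad"):
            similarity_matrix(recs, "N")


class TestSSN:
    def _matrix(self):
        vals = np.array([[100.0, 90, 20], [90, 100, 20], [20, 20, 100]])
        return SimilarityMatrix(ids=["A", "B", "C"], values=vals, kind="seq_full", scale="percent")

    def test_threshold_filters_edges(self):
        g = build_ssn(self._matrix(), 50)
        assert set(map(frozenset, g.edges)) == {frozenset({"A", "B"})}
        assert set(g.nodes) == {"A", "B", "C"}  # isolated node retained

    def test_zero_cutoff_complete_graph(self):
        g = build_ssn(self._matrix(), 0)
        assert g.number_of_edges() == 3

    def test_threshold_outside_scale(self):
        with pytest.raises(ValueError):
            build_ssn(self._matrix(), 101)

    def test_no_self_edges(self):
        g = build_ssn(self._matrix(), 0)
        assert all(a != b for a, b in g.edges)

    def test_nested_thresholds_give_nested_edge_sets(self, cohort):
        mat = similarity_matrix(cohort.records[:8], "full")
        edges = {
            t: set(map(frozenset, build_ssn(mat, t).edges)) for t in (20, 40, 60, 80)
        }
        assert edges[80] <= edges[60] <= edges[40] <= edges[20]
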