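import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from ditps3d.io_model import EnzymeRecord, ProductRef
from ditps3d.seq_analysis import SimilarityMatrix
from ditps3d.stats_corr import (
    AA_ORDER,
    GAAC_GROUPS,
    composition,
    condense,
    correlation_report,
    group_compare,
    pair_partition,
    pair_values,
    pearson,
    preference,
)


class TestComposition:
    def test_small_example(self):
        c = composition("AAW")
        assert c.aac["A"] == pytest.approx(2 / 3)
        assert c.aac["W"] == pytest.approx(1 / 3)
        assert c.gaac["aliphatic"] == pytest.approx(2 / 3)
        assert c.gaac["aromatic"] == pytest.approx(1 / 3)

    def test_all_negative(self):
        assert composition("DEDE").gaac["negative"] == pytest.approx(1.0)

    def test_groups_partition_alphabet(self):
        union = frozenset().union(*GAAC_GROUPS.values())
        assert union == frozenset(AA_ORDER)
        total = sum(len(g) for g in GAAC_GROUPS.values())
        assert total == 20

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.text(alphabet=AA_ORDER, min_size=1, max_size=60))
    def test_frequencies_sum_to_one(self, letters):
        c = composition(letters)
        assert sum(c.aac.values()) == pytest.approx(1.0)
        assert sum(c.gaac.values()) == pytest.approx(1.0)

    def test_x_skipped_with_count(self):
        c = composition("AXXW")
        assert c.n_counted == 2 and c.n_skipped_x == 2
        assert c.aac["A"] == pytest.approx(0.5)

    def test_empty_flag(self):
        c = composition("")
        assert c.empty and all(v == 0.0 for v in c.aac.values())


class TestPreference:
    def test_equal_frequencies(self):
        p = preference("AW", "AAWW")
        assert p.ratio["A"] == pytest.approx(1.0) and p.ratio["W"] == pytest.approx(1.0)

    def test_enrichment_arithmetic(self):
        p = preference("AW", "AAAW")
        assert p.ratio["W"] == pytest.approx(2.0)
        assert p.ratio["A"] == pytest.approx(2 / 3)

    def test_undefined_flag_never_divides(self):
        p = preference("C", "AAAW")
        assert "C" in p.undefined and p.ratio["C"] == 0.0

    def test_self_preference_is_one_over_present_letters(self):
        seq = "MKLVWWYFA"
        p = preference(seq, seq)
        for letter in set(seq):
            assert p.ratio[letter] == pytest.approx(1.0)

    def test_empty_shell_valid(self):
        p = preference("", "AAAW")
        assert all(v == 0.0 for v in p.ratio.values()) and not p.undefined


def _mat(ids, values, kind="seq_full", scale="percent"):
    return SimilarityMatrix(ids=ids, values=np.asarray(values, float), kind=kind, scale=scale)


class TestCondense:
    def test_fixed_pair_order(self):
        m = _mat(["a", "b", "c"], [[100, 10, 20], [10, 100, 30], [20, 30, 100]])
        vals, pairs = condense(m)
        assert pairs == [("a", "b"), ("a", "c"), ("b", "c")]
        assert vals.tolist() == [10.0, 20.0, 30.0]

    def test_deterministic_and_unknown_id_rejected(self):
        v = np.random.default_rng(0).random((3, 3))
        v = (v + v.T) / 2 + np.eye(3)
        m = _mat(["a", "b", "c"], v)
        v1, _ = condense(m)
        v2, _ = condense(m)
        assert np.array_equal(v1, v2)
        with pytest.raises(ValueError):
            condense(m, ["a", "zz"])

    def test_missing_entries_stay_nan(self):
        v = np.array([[100.0, np.nan, 20], [np.nan, 100, 30], [20, 30, 100]])
        vals, pairs = condense(_mat(["a", "b", "c"], v))
        assert np.isnan(vals[0]) and vals[1] == 20.0


class TestPearson:
    def test_perfect_positive(self):
        r, p, n = pearson([1, 2, 3], [2, 4, 6])
        assert r == pytest.approx(1.0) and n == 3

    def test_perfect_negative(self):
        r, _, _ = pearson([1, 2, 3], [3, 2, 1])
        assert r == pytest.approx(-1.0)

    def test_hand_value(self):
        r, _, _ = pearson([1, 2, 3, 4], [1, 3, 2, 4])
        assert r == pytest.approx(0.8)

    def test_matches_two_pass_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            x = rng.normal(size=30)
            y = rng.normal(size=30)
            r, p, n = pearson(x, y)
            # naive two-pass covariance oracle
            mx, my = x.mean(), y.mean()
            cov = float(np.sum((x - mx) * (y - my)))
            oracle = cov / np.sqrt(np.sum((x - mx) ** 2) * np.sum((y - my) ** 2))
            assert r == pytest.approx(oracle, abs=1e-12)
            r_sp, p_sp = sps.pearsonr(x, y)
            assert r == pytest.approx(r_sp, abs=1e-12)
            assert p == pytest.approx(p_sp, rel=1e-8)

    def test_degenerate_variance(self):
        with pytest.raises(ValueError, match="degenerate"):
            pearson([1, 1, 1], [1, 2, 3])

    def test_too_short(self):
        with pytest.raises(ValueError):
            pearson([1, 2], [1, 2])


class TestCorrelationReport:
    def _random_factors(self, seed, n=15):
        rng = np.random.default_rng(seed)
        ids = [f"e{i}" for i in range(n)]
        out = {}
        for kind in ("f1", "f2"):
            v = rng.random((n, n))
            v = (v + v.T) / 2
            np.fill_diagonal(v, 1.0)
            out[kind] = _mat(ids, v, kind=kind, scale="unit")
        return out

    def test_factor_with_itself(self):
        f = self._random_factors(1)
        rep = correlation_report({"a": f["f1"], "b": f["f1"]})
        assert rep.get("a", "b")["r"] == pytest.approx(1.0)

    def test_independent_factors_mostly_uncorrelated(self):
        # n = 15 enzymes -> 105 pairs; |r| < 0.3 in at least 19/20 seeded runs
        hits = sum(
            abs(correlation_report(self._random_factors(seed)).get("f1", "f2")["r"]) < 0.3
            for seed in range(20)
        )
        assert hits >= 19

    def test_order_invariance(self, cohort):
        from ditps3d.seq_analysis import similarity_matrix
        from ditps3d.chem_products import product_similarity_matrix

        recs = cohort.records[:8]
        f = {
            "seq_full": similarity_matrix(recs, "full"),
            "product_dsc": product_similarity_matrix(recs),
        }
        r1 = correlation_report(f).get("seq_full", "product_dsc")["r"]
        recs_rev = list(reversed(recs))
        f2 = {
            "seq_full": similarity_matrix(recs_rev, "full"),
            "product_dsc": product_similarity_matrix(recs_rev),
        }
        r2 = correlation_report(f2).get("seq_full", "product_dsc")["r"]
        assert r1 == pytest.approx(r2, abs=1e-9)

    def test_listwise_deletion(self):
        ids = ["a", "b", "c", "d"]
        v1 = np.ones((4, 4))
        v1[0, 1] = v1[1, 0] = np.nan
        rng = np.random.default_rng(3)
        v2 = rng.random((4, 4))
        v2 = (v2 + v2.T) / 2
        np.fill_diagonal(v2, 1.0)
        v1r = rng.random((4, 4))
        v1 = (v1r + v1r.T) / 2 + v1 * 0  # symmetric with the NaN reinstated
        v1[0, 1] = v1[1, 0] = np.nan
        np.fill_diagonal(v1, 1.0)
        rep = correlation_report(
            {"f1": _mat(ids, v1, "f1", "unit"), "f2": _mat(ids, v2, "f2", "unit")}
        )
        assert rep.get("f1", "f2")["n"] == 5  # 6 pairs minus the missing one


class TestGroupCompare:
    def test_identical_groups_not_significant(self):
        res = group_compare([1, 2, 3], [1, 2, 3])
        assert res["p"] > 0.9

    def test_separated_groups_exact(self):
        res = group_compare([10, 11, 12], [1, 2, 3])
        assert res["U"] == 9.0
        assert res["p"] == pytest.approx(0.1)
        assert res["method"] == "exact"

    def test_exact_matches_full_enumeration(self):
        # all group sizes up to 5+5 with unique values: exact p equals
        # enumeration of the U null distribution
        rng = np.random.default_rng(4)
        for n1, n2 in [(3, 3), (4, 3), (5, 5)]:
            vals = rng.permutation(np.arange(1, n1 + n2 + 1, dtype=float))
            x, y = vals[:n1], vals[n1:]
            res = group_compare(x, y)
            u_obs = res["U"]
            us = []
            for combo in itertools.combinations(range(n1 + n2), n1):
                xs = vals[np.array(combo)]
                ys = np.delete(vals, np.array(combo))
                us.append(sum(1 for a in xs for b in ys if a > b) + 0.5 * sum(
                    1 for a in xs for b in ys if a == b
                ))
            us = np.array(us)
            mean_u = n1 * n2 / 2
            p_enum = np.mean(np.abs(us - mean_u) >= abs(u_obs - mean_u) - 1e-12)
            assert res["p"] == pytest.approx(p_enum, abs=1e-9)

    def test_quartiles(self):
        res = group_compare([1, 2, 3, 4, 5], [1, 2, 3])
        assert res["same"]["median"] == 3.0
        assert res["same"]["q1"] == 2.0 and res["same"]["q3"] == 4.0

    def test_empty_group_fails(self):
        with pytest.raises(ValueError):
            group_compare([], [1, 2, 3])


class TestPairPartition:
    def _rec(self, acc, substrate, skeletons):
        return EnzymeRecord(
            accession=acc,
            sequence="MKLVW",
            substrate=substrate,
            products=[ProductRef(s, "C", s) for s in skeletons],
        )

    def test_same_substrate(self):
        recs = [self._rec("a", "GGPP", ["x"]), self._rec("b", "GGPP", ["y"])]
        same, different = pair_partition(recs, "substrate")
        assert same == [("a", "b")] and different == []

    def test_different_skeletons(self):
        recs = [self._rec("a", "GGPP", ["labdane"]), self._rec("b", "GGPP", ["kaurane"])]
        same, different = pair_partition(recs, "product_skeleton")
        assert different == [("a", "b")]

    def test_multilabel_intersection_rule(self):
        recs = [
            self._rec("a", "GGPP", ["labdane", "abietane"]),
            self._rec("b", "GGPP", ["abietane"]),
        ]
        same, _ = pair_partition(recs, "product_skeleton")
        assert same == [("a", "b")]

    def test_missing_key_excluded_with_warning(self):
        recs = [self._rec("a", "", ["x"]), self._rec("b", "GGPP", ["x"]), self._rec("c", "GGPP", ["x"])]
        with pytest.warns(UserWarning, match="a"):
            same, different = pair_partition(recs, "substrate")
        assert same == [("b", "c")]

    def test_pair_values_drops_missing(self):
        v = np.array([[1.0, np.nan], [np.nan, 1.0]])
        m = _mat(["a", "b"], v, scale="unit")
        assert pair_values(m, [("a", "b")]).size == 0
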