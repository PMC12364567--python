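import itertools
import math

import numpy as np
import pytest

from lipidtraffic.stats import (
    BinaryListPair,
    bh_adjust,
    cv_summary,
    enfc,
    enfc_table,
    floor_pvalue,
    format_pvalue,
    group_test,
    jaccard,
    jtc_pvalue,
    jtc_pvalue_sets,
    mean_phenotype_difference,
    significance_tier,
)


def brute_force_jtc_p(n, k1, k2, m_obs):
    """Dissimilarity-tail p by enumerating all C(n,k1) x C(n,k2) placements."""
    combos1 = np.array(
        [sum(1 << i for i in c) for c in itertools.combinations(range(n), k1)],
        dtype=np.uint64,
    )
    combos2 = np.array(
        [sum(1 << i for i in c) for c in itertools.combinations(range(n), k2)],
        dtype=np.uint64,
    )
    inter = np.bitwise_count(combos1[:, None] & combos2[None, :]).astype(float)
    j = inter / (k1 + k2 - inter)
    j_obs = m_obs / (k1 + k2 - m_obs)
    return float((j <= j_obs + 1e-12).mean())


class TestJaccard:
    def test_counting_example(self):
        universe = [f"v{i}" for i in range(6)]
        pair = BinaryListPair.from_sets({"v1", "v2", "v3"}, {"v2", "v3", "v4"}, universe)
        assert jaccard(pair.a, pair.b) == pytest.approx(0.5)

    def test_identical_and_disjoint(self):
        a = np.array([1, 1, 0, 0], bool)
        assert jaccard(a, a) == 1.0
        assert jaccard(a, ~a) == 0.0

    def test_empty_lists_convention(self):
        z = np.zeros(4, bool)
        with pytest.warns(UserWarning, match="empty"):
            assert jaccard(z, z) == 1.0


class TestJtcPvalue:
    def test_exact_equals_enumeration_small_case(self):
        # universe 6, lists of 3 and 3, intersection 2
        p_oracle = brute_force_jtc_p(6, 3, 3, 2)
        res = jtc_pvalue_sets({"a", "b", "c"}, {"b", "c", "x"}, 6)
        assert res.pvalue == pytest.approx(p_oracle, abs=1e-12)
        assert res.j == pytest.approx(2 / 4)

    def test_identical_lists_give_p_one(self):
        res = jtc_pvalue_sets({"a", "b"}, {"a", "b"}, 10)
        assert res.j == 1.0
        assert res.pvalue == pytest.approx(1.0)

    def test_monte_carlo_deterministic_under_seed(self):
        pair = BinaryListPair.from_sets(set("abc"), set("cde"), list("abcdefgh"))
        r1 = jtc_pvalue(pair, method="monte-carlo", n_null=999, seed=5)
        r2 = jtc_pvalue(pair, method="monte-carlo", n_null=999, seed=5)
        assert r1.pvalue == r2.pvalue

    def test_monte_carlo_close_to_exact(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            n = int(rng.integers(6, 30))
            k1 = int(rng.integers(1, n))
            k2 = int(rng.integers(1, n))
            s1 = set(rng.choice(n, size=k1, replace=False).tolist())
            s2 = set(rng.choice(n, size=k2, replace=False).tolist())
            exact = jtc_pvalue_sets(s1, s2, n).pvalue
            mc = jtc_pvalue_sets(s1, s2, n, method="monte-carlo", n_null=9999,
                                 seed=3).pvalue
            se = math.sqrt(exact * (1 - exact) / 9999)
            assert abs(mc - exact) <= 3 * se + 2 / 10000

    def test_monte_carlo_needs_replicates(self):
        pair = BinaryListPair.from_sets({"a"}, {"b"}, list("abcd"))
        with pytest.raises(ValueError, match="n_null"):
            jtc_pvalue(pair, method="monte-carlo", n_null=50)

    def test_two_sided_at_least_one_sided(self):
        pair = BinaryListPair.from_sets(set("ab"), set("cd"), list("abcdefgh"))
        one = jtc_pvalue(pair).pvalue
        two = jtc_pvalue(pair, two_sided=True).pvalue
        assert two >= one


class TestEnfc:
    def test_worked_example(self):
        r = enfc("v", "c", mu1=2, sigma1=0.2, n1=5, mu0=1, sigma0=0.1, n0=5)
        assert r.fold_change == pytest.approx(2.0)
        assert r.enfc == pytest.approx(math.log(2) / math.sqrt(0.02), rel=1e-9)
        assert r.enfc == pytest.approx(4.901, abs=1e-3)

    def test_equal_means_give_zero(self):
        r = enfc("v", "c", 3.0, 0.5, 5, 3.0, 0.4, 5)
        assert r.enfc == pytest.approx(0.0)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(mu1=2, sigma1=0, n1=5, mu0=1, sigma0=0, n0=5),
            dict(mu1=0, sigma1=0.1, n1=5, mu0=1, sigma0=0.1, n0=5),
            dict(mu1=2, sigma1=0.1, n1=5, mu0=0, sigma0=0.1, n0=5),
        ],
    )
    def test_incalculable_cases(self, kwargs):
        assert enfc("v", "c", **kwargs).incalculable

    def test_antisymmetric_under_group_swap(self):
        fwd = enfc("v", "c", 2.5, 0.3, 6, 1.5, 0.2, 6)
        rev = enfc("v", "c", 1.5, 0.2, 6, 2.5, 0.3, 6)
        assert fwd.enfc == pytest.approx(-rev.enfc)
        assert np.sign(fwd.enfc) == np.sign(math.log(fwd.fold_change))

    def test_table_over_toy_study(self, toy_study):
        table, design, _ = toy_study
        t = enfc_table(table, design, "F", "M")
        assert set(t["compartment"]) == {"liver", "serum"}
        pc = t[(t.variable == "PC(34:2)") & (t.compartment == "liver")].iloc[0]
        assert not pc.incalculable
        # TG(48:1) undetected in males -> incalculable
        tg = t[(t.variable == "TG(48:1)") & (t.compartment == "liver")].iloc[0]
        assert tg.incalculable


class TestCv:
    def _study(self, values_by_sample):
        import pandas as pd

        from lipidtraffic.dataio import AbundanceTable, StudyDesign

        ids = list(values_by_sample.index)
        table = AbundanceTable(values_by_sample)
        design = StudyDesign(
            pd.DataFrame(
                {"phenotype": ["G"] * len(ids), "compartment": ["c"] * len(ids)},
                index=ids,
            )
        )
        return table, design

    def test_direct_example(self):
        import pandas as pd

        df = pd.DataFrame({"PC(34:2)": [1.0, 2.0, 3.0]}, index=["a", "b", "c"])
        table, design = self._study(df)
        s = cv_summary(table, design, "G")
        assert s["per_variable_cv"]["PC(34:2)"] == pytest.approx(50.0)

    def test_constant_variable_and_mean(self):
        import pandas as pd

        df = pd.DataFrame(
            {"PC(34:2)": [5.0, 5.0, 5.0], "TG(48:1)": [10.0, 12.0, 8.0]},
            index=["a", "b", "c"],
        )
        table, design = self._study(df)
        s = cv_summary(table, design, "G")
        assert s["per_variable_cv"]["PC(34:2)"] == 0.0
        expected_tg = float(np.std([10, 12, 8], ddof=1) / 10 * 100)
        assert s["mean_cv"] == pytest.approx((0.0 + expected_tg) / 2)

    def test_scale_invariance(self):
        import pandas as pd

        rng = np.random.default_rng(3)
        df = pd.DataFrame(
            rng.lognormal(1, 0.4, size=(6, 4)),
            index=[f"s{i}" for i in range(6)],
            columns=["PC(34:2)", "PC(36:2)", "TG(48:1)", "SM(34:1)"],
        )
        t1, d1 = self._study(df)
        t2, d2 = self._study(df * 7.3)
        cv1 = cv_summary(t1, d1, "G")["per_variable_cv"]
        cv2 = cv_summary(t2, d2, "G")["per_variable_cv"]
        np.testing.assert_allclose(cv1, cv2)

    def test_mean_phenotype_difference(self):
        import pandas as pd

        from lipidtraffic.dataio import AbundanceTable, StudyDesign

        ids = [f"s{i}" for i in range(8)]
        df = pd.DataFrame({"PC(34:2)": [10.0] * 4 + [12.0] * 4}, index=ids)
        design = StudyDesign(
            pd.DataFrame(
                {"phenotype": ["F"] * 4 + ["M"] * 4, "compartment": ["c"] * 8},
                index=ids,
            )
        )
        d = mean_phenotype_difference(AbundanceTable(df), design, "F", "M")
        assert d == pytest.approx(abs(10 - 12) / 11 * 100)


class TestGroupTest:
    def test_identical_samples_give_p_one(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert group_test(x, x) == pytest.approx(1.0)

    def test_complete_separation_matches_enumeration(self):
        """Exact two-sided rank p for complete separation at n = 8 vs 8.

        Enumerates all C(16, 8) rank assignments: only the two fully
        separated ones are as extreme, so p = 2 / 12870.
        """
        x = list(range(1, 9))
        y = list(range(11, 19))
        n_total = math.comb(16, 8)
        # enumeration oracle over rank sums
        ranks = range(1, 17)
        u_obs = 0  # all of x below all of y
        count = 0
        for combo in itertools.combinations(ranks, 8):
            r = sum(combo) - 8 * 9 // 2  # Mann-Whitney U of the combo
            if r <= u_obs or r >= 64 - u_obs:
                count += 1
        p_oracle = count / n_total
        assert p_oracle == pytest.approx(2 / 12870)
        assert group_test(x, y) == pytest.approx(p_oracle, rel=1e-9)

    def test_all_ties_warn(self):
        with pytest.warns(UserWarning, match="tied"):
            assert group_test([2.0] * 4, [2.0] * 5) == 1.0

    def test_minimum_group_size(self):
        with pytest.raises(ValueError):
            group_test([1, 2], [3, 4, 5])

    @pytest.mark.parametrize(
        "p, tier",
        [
            (0.5, ""), (0.08, "*"), (0.03, "+"), (0.005, "**"),
            (5e-4, "***"), (5e-5, "****"),
        ],
    )
    def test_significance_tiers(self, p, tier):
        assert significance_tier(p) == tier


def test_pvalue_floor_and_format():
    assert floor_pvalue(1e-20) == pytest.approx(2.2e-16)
    assert format_pvalue(1e-20) == "<2.2e-16"
    assert floor_pvalue(0.01) == 0.01


def test_bh_adjust_order_preserving():
    p = np.array([0.001, 0.01, 0.04, 0.2, np.nan])
    adj = bh_adjust(p)
    assert np.isnan(adj[-1])
    assert (np.diff(adj[:-1]) >= -1e-12).all()
    assert (adj[:-1] >= p[:-1] - 1e-12).all()
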