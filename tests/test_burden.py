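import warnings
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from regulaburden import burden
from regulaburden.burden import (
    ContingencyTable,
    c_alpha_statistic,
    c_alpha_test,
    cast,
    directional_cast,
    fisher_exact,
    fisher_pvalues_for_margins,
    weighted_sum_test,
)
from regulaburden.errors import ConfigurationError, ValidationError


def oracle_fisher(a, b, c, d, sidedness="two", alternative="greater"):
    """Independent enumeration oracle over all tables with the observed
    margins, using scipy's hypergeometric pmf (float route, vs the
    implementation's exact-integer route)."""
    n1, n2, K = a + b, c + d, a + c
    N = n1 + n2
    kmin, kmax = max(0, K - n2), min(K, n1)
    ks = np.arange(kmin, kmax + 1)
    pmf = stats.hypergeom.pmf(ks, N, K, n1)
    obs = pmf[ks == a][0]
    if sidedness == "two":
        return float(pmf[pmf <= obs * (1 + 1e-7)].sum())
    if alternative == "greater":
        return float(pmf[ks >= a].sum())
    return float(pmf[ks <= a].sum())


class TestFisherExact:
    @pytest.mark.parametrize(
        "table,expected",
        [
            ((16, 179, 9, 184), 0.2142),
            ((6, 189, 0, 193), 0.0301),
            ((1, 194, 7, 186), 0.0364),
            ((0, 195, 5, 188), 0.0297),
        ],
    )
    def test_published_pvalues(self, table, expected):
        p = fisher_exact(ContingencyTable(*table), sidedness="two")
        assert round(p, 4) == expected

    def test_symmetric_table_is_one(self):
        assert fisher_exact(ContingencyTable(5, 5, 5, 5)) == pytest.approx(1.0)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError):
            ContingencyTable(-1, 5, 5, 5)

    def test_no_carriers_warns_p_one(self):
        with pytest.warns(UserWarning, match="degenerate"):
            assert fisher_exact(ContingencyTable(0, 10, 0, 10)) == 1.0

    def test_matches_scipy_convention(self):
        # scipy's two-sided Fisher uses the same minimum-likelihood rule
        rng = np.random.default_rng(0)
        for _ in range(50):
            a, b, c, d = rng.integers(0, 30, size=4)
            if a + c == 0 or b + d == 0:
                continue
            ours = fisher_exact(ContingencyTable(int(a), int(b), int(c), int(d)))
            _, theirs = stats.fisher_exact([[a, b], [c, d]])
            assert ours == pytest.approx(theirs, abs=1e-10)

    def test_enumeration_oracle_small(self):
        # exhaustive margins with N <= 30 (the full N <= 60 sweep runs in
        # the acceptance suite)
        for n1 in range(1, 16):
            for n2 in range(1, 16):
                for K in range(1, n1 + n2):
                    ks, p_g, p_l, p_two = fisher_pvalues_for_margins(n1, n2, K)
                    for i, a in enumerate(ks):
                        b, c, d = n1 - a, K - a, n2 - (K - a)
                        assert p_two[i] == pytest.approx(
                            oracle_fisher(a, b, c, d, "two"), abs=1e-12
                        )
                        assert p_g[i] == pytest.approx(
                            oracle_fisher(a, b, c, d, "one", "greater"), abs=1e-12
                        )
                        assert p_l[i] == pytest.approx(
                            oracle_fisher(a, b, c, d, "one", "less"), abs=1e-12
                        )

    @given(
        a=st.integers(0, 25), b=st.integers(0, 25),
        c=st.integers(0, 25), d=st.integers(0, 25),
    )
    @settings(max_examples=200, deadline=None)
    def test_two_sided_at_least_min_one_sided(self, a, b, c, d):
        t = ContingencyTable(a, b, c, d)
        if t.K == 0 or t.K == t.N or t.n1 == 0 or t.n2 == 0:
            return
        p2 = fisher_exact(t, "two")
        p1 = min(fisher_exact(t, "one", "greater"), fisher_exact(t, "one", "less"))
        assert p2 >= p1 - 1e-12


class TestCast:
    def test_bundled_fixture(self, rare_catalog, carriers, cohorts):
        res = cast(rare_catalog, carriers, cohorts)
        assert (res.table.a, res.table.b, res.table.c, res.table.d) == (16, 179, 9, 184)
        assert round(res.p_value, 4) == 0.2142
        assert len(res.variants_used) == 17

    def test_no_rare_variants_degenerate(self, common_catalog, carriers, cohorts):
        with pytest.warns(UserWarning, match="degenerate"):
            res = cast(common_catalog, carriers, cohorts)
        assert res.degenerate and res.p_value == 1.0

    def test_single_carrier_matches_oracle(self, cohorts):
        import pandas as pd

        from regulaburden.catalog import CarrierTable, GenotypeCounts, VariantRecord

        rec = VariantRecord("v1", -10, "A", "G", {"HHDL": GenotypeCounts(1, 0)})
        rec.freq_class = "rare"
        df = pd.DataFrame(
            {"individual_id": ["H1"], "cohort": ["HHDL"], "variant_id": ["v1"]}
        )
        table = CarrierTable.from_long(df)
        res = cast([rec], table, cohorts)
        assert res.p_value == pytest.approx(oracle_fisher(1, 194, 0, 193), abs=1e-12)


class TestDirectionalCast:
    @pytest.mark.parametrize(
        "direction,exclusive,carriers_expected,p_expected,n_variants",
        [
            ("decrease", False, (6, 0), 0.0301, 4),
            ("increase", False, (1, 7), 0.0364, 5),
            ("decrease", True, (6, 0), 0.0301, 4),
            ("increase", True, (0, 5), 0.0297, 4),
        ],
    )
    def test_published_rows(
        self, rare_catalog, carriers, functional_calls, cohorts,
        direction, exclusive, carriers_expected, p_expected, n_variants,
    ):
        res = directional_cast(
            rare_catalog, carriers, functional_calls, direction,
            exclusive=exclusive, cohorts=cohorts,
        )
        assert (res.table.a, res.table.c) == carriers_expected
        assert round(res.p_value, 4) == p_expected
        assert len(res.variants_used) == n_variants

    def test_exclusive_subset_property(self, rare_catalog, carriers, functional_calls, cohorts):
        for direction in ("decrease", "increase"):
            full = directional_cast(
                rare_catalog, carriers, functional_calls, direction, cohorts=cohorts
            )
            excl = directional_cast(
                rare_catalog, carriers, functional_calls, direction,
                exclusive=True, cohorts=cohorts,
            )
            assert excl.variants_used <= full.variants_used
            assert excl.table.a <= full.table.a
            assert excl.table.c <= full.table.c

    def test_dual_direction_carrier_in_both_tests(
        self, rare_catalog, carriers, functional_calls, cohorts
    ):
        # the individual carrying both a decrease and an increase variant
        # contributes to both directional carrier counts
        dec = directional_cast(
            rare_catalog, carriers, functional_calls, "decrease", cohorts=cohorts
        )
        inc = directional_cast(
            rare_catalog, carriers, functional_calls, "increase", cohorts=cohorts
        )
        assert dec.table.a == 6 and inc.table.a == 1

    def test_missing_call_is_configuration_error(
        self, rare_catalog, carriers, functional_calls, cohorts
    ):
        partial = {k: v for k, v in functional_calls.items() if k != "-1487A>G"}
        with pytest.raises(ConfigurationError, match="-1487A>G"):
            directional_cast(rare_catalog, carriers, partial, "decrease", cohorts=cohorts)

    def test_one_sided_option(self, rare_catalog, carriers, functional_calls, cohorts):
        two = directional_cast(
            rare_catalog, carriers, functional_calls, "decrease", cohorts=cohorts
        )
        one = directional_cast(
            rare_catalog, carriers, functional_calls, "decrease",
            cohorts=cohorts, sidedness="one",
        )
        assert one.p_value <= two.p_value


class TestWeightedSum:
    def test_no_carriers_p_one(self):
        res = weighted_sum_test(np.zeros((20, 3)), np.arange(20) < 10, 100, seed=1)
        assert res.p_value == 1.0

    def test_all_carriers_exchangeable_p_one(self):
        # every individual carries the variant: scores identical, ranks tie,
        # every permutation reproduces the observed statistic
        G = np.ones((20, 1))
        res = weighted_sum_test(G, np.arange(20) < 10, 200, seed=1)
        assert res.p_value == 1.0

    def test_symmetric_split_not_significant(self):
        G = np.zeros((20, 1))
        G[:2, 0] = 1  # 2 carriers among cases
        G[10:12, 0] = 1  # 2 among controls
        res = weighted_sum_test(G, np.arange(20) < 10, 2000, seed=3)
        assert res.p_value > 0.3

    def test_enrichment_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(1)
        n = 100
        G = np.zeros((2 * n, 4))
        case_rows = rng.choice(n, 20, replace=False)
        ctrl_rows = n + rng.choice(n, 2, replace=False)
        for i, r in enumerate(np.concatenate([case_rows, ctrl_rows])):
            G[r, i % 4] = 1
        labels = np.arange(2 * n) < n
        res = weighted_sum_test(G, labels, 4000, seed=7)

        # independent brute-force permutation oracle (plain loops)
        def score(lab):
            ctrl = ~lab
            q = (G[ctrl].sum(axis=0) + 1) / (2 * ctrl.sum() + 2)
            w = np.sqrt(ctrl.sum() * q * (1 - q))
            s = (G / w).sum(axis=1)
            return stats.rankdata(s)[lab].sum()

        obs = score(labels)
        rng2 = np.random.default_rng(99)
        hits = 0
        B = 4000
        lab = labels.copy()
        for _ in range(B):
            rng2.shuffle(lab)
            if score(lab) >= obs:
                hits += 1
        p_oracle = (hits + 1) / (B + 1)
        se = np.sqrt(p_oracle * (1 - p_oracle) / B)
        assert res.p_value == pytest.approx(p_oracle, abs=max(5 * se, 5e-4))
        assert res.p_value < 0.01  # strong enrichment detected

    def test_seed_required(self):
        with pytest.raises(ConfigurationError):
            weighted_sum_test(np.ones((4, 1)), np.array([1, 1, 0, 0], bool), 10)


class TestCAlpha:
    def test_closed_form_at_expectation(self):
        # every variant split exactly at expectation: each contributes
        # -n_v p0 (1 - p0)
        y = np.array([1.0, 2.0])
        n = np.array([2.0, 4.0])
        p0 = 0.5
        assert c_alpha_statistic(y, n, p0) == pytest.approx(-(2 + 4) * 0.25)

    def test_singleton_exact_enumeration(self):
        # one variant carried by one individual: T has exactly two values
        n1, n2 = 12, 8
        X = np.zeros((n1 + n2, 1), bool)
        X[0, 0] = True  # carrier is a case
        labels = np.arange(n1 + n2) < n1
        p0 = n1 / (n1 + n2)
        t_case = c_alpha_statistic([1], [1], p0)
        t_ctrl = c_alpha_statistic([0], [1], p0)
        assert len({round(t_case, 12), round(t_ctrl, 12)}) == 2
        # exact permutation null: carrier lands in cases w.p. n1/N
        exact_p = n1 / (n1 + n2) if t_case >= t_ctrl else 1.0
        res = c_alpha_test(X, labels, 20_000, seed=5)
        assert res.p_value == pytest.approx(exact_p, abs=0.02)

    def test_bidirectional_contrast_with_cast(self, cohorts):
        # variants exclusively in one cohort each inflate T while the
        # undirected collapsed table stays balanced
        rng = np.random.default_rng(11)
        n = 100
        X = np.zeros((2 * n, 10), bool)
        for v in range(5):  # 4 carriers each, all in cohort 1
            X[rng.choice(n, 4, replace=False), v] = True
        for v in range(5, 10):  # 4 carriers each, all in cohort 2
            X[n + rng.choice(n, 4, replace=False), v] = True
        labels = np.arange(2 * n) < n
        res = c_alpha_test(X, labels, 2000, seed=2)
        assert res.p_value < 0.05

        a = int((X[:n].any(axis=1)).sum())
        c = int((X[n:].any(axis=1)).sum())
        p_cast = fisher_exact(ContingencyTable(a, n - a, c, n - c))
        assert p_cast > 0.5

    def test_no_carriers_p_one(self):
        res = c_alpha_test(np.zeros((10, 2), bool), np.arange(10) < 5, 100, seed=1)
        assert res.p_value == 1.0
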