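"""FFQ conversion, median regression, Fisher enrichment, group tests, HFD."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import minimize
from statsmodels.regression.quantile_regression import QuantReg

from microstrat.associations import (
    FfqTable, combination_enrichment, convert_ffq_frequencies, fisher_exact,
    group_tests, hfd_index, macronutrient_summary, median_regression,
)


class TestFfqConversion:
    def test_worked_examples(self):
        raw = pd.DataFrame({
            "milk": ["2 times per day", "1–3 times per week"],
            "fish": ["never or less than once a week", "4 or more times per day"],
        }, index=["s1", "s2"])
        daily = convert_ffq_frequencies(raw)
        assert daily.loc["s1", "milk"] == 2.0
        assert daily.loc["s2", "milk"] == pytest.approx(2.0 / 7.0)
        assert daily.loc["s1", "fish"] == 0.0
        assert daily.loc["s2", "fish"] == 4.0

    def test_unknown_category_listed(self):
        raw = pd.DataFrame({"milk": ["sometimes"]}, index=["s1"])
        with pytest.raises(ValueError, match="sometimes"):
            convert_ffq_frequencies(raw)

    def test_custom_dialect(self):
        raw = pd.DataFrame({"tea": ["daily"]}, index=["s1"])
        out = convert_ffq_frequencies(raw, dialect={"daily": 1.0})
        assert out.loc["s1", "tea"] == 1.0


def _ffq(consumption, hv=None, macros=None):
    cons = pd.DataFrame(consumption)
    cons.index = [f"s{i}" for i in range(cons.shape[0])]
    foods = [f"f{i}" for i in range(cons.shape[1])]
    cons.columns = foods
    n = len(foods)
    ann = pd.DataFrame({
        "group": ["g"] * n,
        "health_value": hv if hv is not None else [1.0] * n,
        "protein_g": [0.0] * n,
        "fat_g": [0.0] * n,
        "carb_g": [10.0] * n,
        "fibre_g": [0.0] * n,
        "kcal": [40.0] * n,
    }, index=foods)
    if macros:
        for k, v in macros.items():
            ann[k] = v
    return FfqTable(cons, ann)


class TestHfd:
    def test_single_food_zero(self):
        assert hfd_index(_ffq([[5.0, 0.0]])).iloc[0] == pytest.approx(0.0)

    def test_equal_shares_unit_health(self):
        for n in (2, 4, 10):
            ffq = _ffq([[1.0] * n])
            assert hfd_index(ffq).iloc[0] == pytest.approx(1 - 1 / n)

    def test_weighted_example(self):
        ffq = _ffq([[1.0, 1.0]], hv=[1.0, 0.0])
        assert hfd_index(ffq).iloc[0] == pytest.approx(0.25)

    def test_zero_total_named(self):
        with pytest.raises(ValueError, match="s1"):
            hfd_index(_ffq([[1.0, 1.0], [0.0, 0.0]]))

    @settings(derandomize=True, max_examples=50)
    @given(
        cons=st.lists(st.floats(0.01, 10.0), min_size=2, max_size=8),
        scale=st.floats(0.1, 50.0),
    )
    def test_bounds_and_scale_invariance(self, cons, scale):
        ffq = _ffq([cons])
        h = hfd_index(ffq).iloc[0]
        assert 0.0 <= h <= 1 - 1 / len(cons) + 1e-12
        scaled = _ffq([[c * scale for c in cons]])
        assert hfd_index(scaled).iloc[0] == pytest.approx(h, rel=1e-9)


class TestMacronutrients:
    def test_pure_carbohydrate(self):
        ffq = _ffq([[2.0, 1.0]])
        out = macronutrient_summary(ffq)
        assert out["carbohydrate_pct"].iloc[0] == pytest.approx(100.0)

    def test_protein_fat_split(self):
        ffq = _ffq([[1.0, 1.0]], macros={
            "protein_g": [50.0, 0.0], "fat_g": [0.0, 50.0],
            "carb_g": [0.0, 0.0], "kcal": [200.0, 450.0],
        })
        out = macronutrient_summary(ffq)
        assert out["protein_pct"].iloc[0] == pytest.approx(100 * 200 / 650)
        assert out["fat_pct"].iloc[0] == pytest.approx(100 * 450 / 650)

    def test_fibre_per_1000_kcal(self):
        ffq = _ffq([[1.0]], macros={"carb_g": [500.0], "kcal": [2000.0],
                                    "fibre_g": [10.0]})
        out = macronutrient_summary(ffq)
        assert out["fibre_g_per_1000kcal"].iloc[0] == pytest.approx(5.0)

    def test_zero_kcal_rejected(self):
        ffq = _ffq([[1.0]], macros={"kcal": [0.0]})
        with pytest.raises(ValueError, match="kcal"):
            macronutrient_summary(ffq)


class TestMedianRegression:
    def test_noiseless_recovery(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=30)
        age = np.full(30, 9.0)
        y = 2.0 * x
        row = median_regression(y, x, age, n_boot=50, seed=0)
        assert row.beta == pytest.approx(2.0, abs=1e-6)
        assert row.rc_sd == pytest.approx(2.0 * np.std(x, ddof=1), abs=1e-6)
        assert row.rc_range == pytest.approx(2.0 * np.ptp(x), abs=1e-6)

    def test_matches_brute_force_minimizer(self):
        rng = np.random.default_rng(1)
        n = 15
        x = rng.normal(size=n)
        age = rng.uniform(6, 12, n)
        y = 1.5 * x - 0.2 * age + rng.standard_cauchy(n) * 0.3
        row = median_regression(y, x, age, n_boot=10, seed=0)

        def objective(b):
            r = y - b[0] - b[1] * x - b[2] * age
            return np.abs(r).sum() * 0.5

        best = None
        for start in ([0, 0, 0], [1, 1, 0], [-1, 2, -1]):
            res = minimize(objective, start, method="Nelder-Mead",
                           options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 20000})
            if best is None or res.fun < best.fun:
                best = res
        # LP optimum must not exceed the derivative-free optimum
        from microstrat.associations import _median_fit
        X = np.column_stack([np.ones(n), x, age])
        beta_lp = _median_fit(X, y)
        assert objective(beta_lp) <= best.fun + 1e-8
        assert row.beta == pytest.approx(best.x[1], abs=1e-4)

    def test_matches_statsmodels_quantreg(self):
        rng = np.random.default_rng(2)
        n = 60
        x = rng.normal(size=n)
        age = rng.uniform(6, 12, n)
        y = 0.8 * x + 0.3 * age + rng.laplace(size=n)
        row = median_regression(y, x, age, n_boot=10, seed=0)
        X = pd.DataFrame({"const": 1.0, "x": x, "age": age})
        ref = QuantReg(y, X).fit(q=0.5)
        assert row.beta == pytest.approx(ref.params["x"], abs=1e-4)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=25)
        age = rng.uniform(6, 12, 25)
        y = 1.2 * x + rng.laplace(size=25)
        r1 = median_regression(y, x, age, n_boot=10, seed=0)
        r2 = median_regression(y, 4.0 * x, age, n_boot=10, seed=0)
        assert r2.beta == pytest.approx(r1.beta / 4.0, abs=1e-8)
        assert r2.rc_sd == pytest.approx(r1.rc_sd, abs=1e-8)
        assert r2.rc_range == pytest.approx(r1.rc_range, abs=1e-8)

    def test_too_few_cases(self):
        with pytest.raises(ValueError, match="complete cases"):
            median_regression(np.ones(5), np.arange(5.0), np.ones(5), n_boot=10)

    def test_nan_markers_dropped_with_warning(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=20)
        y = x.copy()
        y[0] = np.nan
        with pytest.warns(UserWarning, match="dropped 1"):
            row = median_regression(y, x, np.ones(20), n_boot=10, seed=0)
        assert row.n == 19

    def test_rankscore_inference(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=80)
        age = rng.uniform(6, 12, 80)
        y = 2.0 * x + rng.laplace(size=80)
        row = median_regression(y, x, age, method="rankscore")
        assert row.p_value < 0.001


def _oracle_fisher(table):
    """Exact-integer enumeration oracle for the 2x2 Fisher test."""
    (a, b), (c, d) = table
    n, r1, c1 = a + b + c + d, a + b, a + c
    kmin, kmax = max(0, r1 + c1 - n), min(r1, c1)
    weights = {k: math.comb(c1, k) * math.comb(n - c1, r1 - k)
               for k in range(kmin, kmax + 1)}
    total = math.comb(n, r1)
    w_obs = weights[a]
    if a >= r1 * c1 / n:
        one = sum(w for k, w in weights.items() if k >= a) / total
    else:
        one = sum(w for k, w in weights.items() if k <= a) / total
    two = sum(w for w in weights.values() if w <= w_obs) / total
    return one, two


class TestFisherExact:
    def test_diagonal_three(self):
        r = fisher_exact([[3, 0], [0, 3]])
        assert r.p_two_sided == pytest.approx(0.1)     # 2 / C(6,3)
        assert r.p_one_sided == pytest.approx(0.05)

    def test_balanced_table_p_one(self):
        r = fisher_exact([[5, 5], [5, 5]])
        assert r.p_two_sided == pytest.approx(1.0)

    def test_seven_vs_zero(self):
        r = fisher_exact([[7, 29], [0, 34]])
        assert r.p_one_sided == pytest.approx(0.00696, abs=5e-5)

    def test_haldane_odds_ratio(self):
        r = fisher_exact([[5, 0], [0, 5]])
        assert r.odds_ratio == pytest.approx((5.5 * 5.5) / (0.5 * 0.5))

    def test_non_integer_rejected(self):
        with pytest.raises(ValueError, match="integer"):
            fisher_exact([[1.5, 2], [3, 4]])

    def test_random_tables_match_enumeration(self):
        rng = np.random.default_rng(6)
        for _ in range(200):
            t = rng.integers(0, 12, (2, 2))
            if t.sum() == 0:
                continue
            mine = fisher_exact(t)
            one, two = _oracle_fisher(t.tolist())
            assert mine.p_one_sided == pytest.approx(one, abs=1e-10)
            assert mine.p_two_sided == pytest.approx(two, abs=1e-8)


class TestCombinationEnrichment:
    def _labels(self):
        samples = [f"P{i}.T{t}" for i in range(10) for t in (1, 3)]
        subj = pd.Series([s.split(".")[0] for s in samples], index=samples)
        states = pd.Series(["C4" if int(s[1]) < 5 else "C1" for s in samples], index=samples)
        diets = pd.Series(["D2" if int(s[1]) < 5 else "D1" for s in samples], index=samples)
        return samples, subj, states, diets

    def test_perfect_association_minimal_p(self):
        samples, subj, states, diets = self._labels()
        pheno = pd.Series([int(s[1]) < 5 for s in samples], index=samples)
        res = combination_enrichment(states, diets, pheno, {"C4"}, {"D2"}, subj)
        assert res.table.tolist() == [[5, 0], [0, 5]]
        assert res.p_one_sided == pytest.approx(1 / math.comb(10, 5))

    def test_any_sample_rule_idempotent(self):
        samples, subj, states, diets = self._labels()
        # subject P0 in combination only at T1: still counted once
        states.loc["P0.T3"] = "C1"
        pheno = pd.Series([int(s[1]) < 5 for s in samples], index=samples)
        res = combination_enrichment(states, diets, pheno, {"C4"}, {"D2"}, subj)
        assert res.table[0, 0] == 5

    def test_independent_phenotype_p_uniform(self):
        rng = np.random.default_rng(7)
        samples, subj, states, diets = self._labels()
        ps = []
        for _ in range(300):
            pheno = pd.Series(rng.random(20) < 0.5, index=samples)
            ps.append(combination_enrichment(states, diets, pheno,
                                             {"C4"}, {"D2"}, subj).p_two_sided)
        # discrete p-values: super-uniform under the null
        assert np.mean(np.asarray(ps) <= 0.05) <= 0.08


class TestGroupTests:
    def _features(self, rng, shift=0.0):
        a = rng.gamma(2, 1, (10, 6))
        b = rng.gamma(2, 1, (10, 6))
        b[:, 0] += shift
        X = pd.DataFrame(np.vstack([a, b]), index=[f"s{i}" for i in range(20)],
                         columns=[f"g{i}" for i in range(6)])
        groups = pd.Series(["A"] * 10 + ["B"] * 10, index=X.index)
        return X, groups

    def test_identical_groups_p_one(self):
        rng = np.random.default_rng(8)
        X, groups = self._features(rng)
        X.iloc[10:] = X.iloc[:10].to_numpy()
        out = group_tests(X, groups)
        assert (out["p"].dropna() >= 0.99).all()

    def test_shifted_feature_most_significant(self):
        rng = np.random.default_rng(9)
        X, groups = self._features(rng, shift=50.0)
        out = group_tests(X, groups).set_index("feature")
        assert out["p_adjusted"].idxmin() == "g0"

    def test_bh_step_up_arithmetic(self):
        rng = np.random.default_rng(10)
        X, groups = self._features(rng)
        out = group_tests(X, groups)
        from statsmodels.stats.multitest import multipletests
        expected = multipletests(out["p"], method="fdr_bh")[1]
        assert np.allclose(out["p_adjusted"], expected)
        # worked example of the step-up rule
        assert np.allclose(multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")[1], 0.04)

    def test_three_groups_kruskal(self):
        rng = np.random.default_rng(11)
        X, _ = self._features(rng)
        groups = pd.Series(["A"] * 7 + ["B"] * 7 + ["C"] * 6, index=X.index)
        out = group_tests(X, groups)
        assert (out["test"].unique() == ["kruskal-wallis"]).all()

    def test_paired_wilcoxon(self):
        rng = np.random.default_rng(12)
        X, groups = self._features(rng, shift=3.0)
        pairing = pd.Series([f"P{i % 10}" for i in range(20)], index=X.index)
        out = group_tests(X, groups, pairing=pairing)
        assert (out["test"] == "wilcoxon-paired").all()
        assert out.set_index("feature")["p"]["g0"] < 0.05

    def test_incomplete_pairing_rejected(self):
        rng = np.random.default_rng(13)
        X, groups = self._features(rng)
        pairing = pd.Series([f"P{i}" for i in range(20)], index=X.index)
        with pytest.raises(ValueError, match="pair"):
            group_tests(X, groups, pairing=pairing)

    def test_bh_adjustment_monotone_and_above_raw(self):
        rng = np.random.default_rng(14)
        X, groups = self._features(rng, shift=5.0)
        out = group_tests(X, groups).dropna(subset=["p"]).sort_values("p")
        assert (out["p_adjusted"].to_numpy() >= out["p"].to_numpy() - 1e-12).all()
        assert (np.diff(out["p_adjusted"].to_numpy()) >= -1e-12).all()
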