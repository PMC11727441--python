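"""Group-comparison statistics: chi-square, routing, ANCOVA/LSD, FDR."""

import numpy as np
import pandas as pd
import pytest

import oracles
from braingraph import chi_square_test, normality_gate, omnibus_and_pairwise, spearman_fdr
from braingraph.stats import ancova_lsd, bonferroni, fdr_bh


class TestChiSquare:
    def test_side_of_tinnitus_worked_example(self):
        chi2, df, p = chi_square_test([[5, 9, 14], [10, 8, 5]])
        assert chi2 == pytest.approx(5.552, abs=5e-4)
        assert df == 2

    def test_identical_row_proportions_give_zero(self):
        chi2, _, p = chi_square_test([[10, 20, 30], [20, 40, 60]])
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_2x2_closed_form(self):
        rng = np.random.default_rng(19)
        for _ in range(20):
            a, b, c, d = rng.integers(1, 40, size=4)
            chi2, df, _ = chi_square_test([[a, b], [c, d]])
            assert df == 1
            assert chi2 == pytest.approx(oracles.chi2_2x2(a, b, c, d), rel=1e-12)

    def test_invariances(self):
        t = np.array([[5, 9, 14], [10, 8, 5]])
        base = chi_square_test(t)[0]
        assert chi_square_test(t[:, ::-1])[0] == pytest.approx(base)
        assert chi_square_test(t[::-1])[0] == pytest.approx(base)
        assert chi_square_test(3 * t)[0] == pytest.approx(3 * base)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="zero margin"):
            chi_square_test([[0, 0], [3, 4]])


class TestNormalityGate:
    def test_discrete_grid_sample_is_non_normal(self):
        values = np.tile([0.0, 1.0, 2.0], 20)
        groups = np.repeat(["A", "B"], 30)
        assert normality_gate(values, groups) == "non-normal"

    def test_gaussian_samples_usually_pass(self):
        passed = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            values = rng.standard_normal(500)
            passed += normality_gate(values, np.repeat("A", 500)) == "normal"
        assert passed >= 90  # level of the Shapiro-Wilk test at alpha=0.05

    def test_routing_contract(self):
        rng = np.random.default_rng(4)
        skewed = np.exp(rng.standard_normal(60) * 2)
        groups = np.repeat(["A", "B", "C"], 20)
        row = omnibus_and_pairwise(skewed, groups, route="auto",
                                   group_levels=("A", "B", "C"))
        assert row.route == "kruskal"
        assert row.stat_name == "H"

    def test_tiny_group_rejected(self):
        with pytest.raises(ValueError, match="n=2 < 3"):
            normality_gate([1.0, 2.0, 3.0, 4.0, 5.0], ["A", "A", "A", "B", "B"])


class TestAncovaLSD:
    def _simulate(self, seed, effect=0.0, n=25):
        rng = np.random.default_rng(seed)
        groups = np.repeat(["PT", "ROT", "HC"], n)
        cov = pd.DataFrame({
            "age": rng.normal(40, 10, 3 * n),
            "sex": rng.integers(0, 2, 3 * n).astype(float),
            "avg_ht": rng.normal(15, 6, 3 * n),
            "ht_8k": rng.normal(20, 8, 3 * n),
        })
        y = rng.standard_normal(3 * n) + 0.02 * cov["age"] + effect * (groups == "ROT")
        return np.asarray(y), groups, cov

    def test_group_f_matches_statsmodels_formula_anova(self):
        """Model-reduction F for the group factor must agree with an
        independent formula-interface ANCOVA fit."""
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        y, groups, cov = self._simulate(seed=1, effect=0.5)
        row = ancova_lsd(y, groups, cov)
        df = cov.assign(y=y, group=groups)
        fit = smf.ols("y ~ C(group) + age + sex + avg_ht + ht_8k", data=df).fit()
        table = anova_lm(fit, typ=2)
        assert row.statistic == pytest.approx(table.loc["C(group)", "F"], abs=1e-6)
        assert row.p_value == pytest.approx(table.loc["C(group)", "PR(>F)"], abs=1e-9)

    def test_pairwise_keys_and_range(self):
        y, groups, cov = self._simulate(seed=2)
        row = ancova_lsd(y, groups, cov)
        assert set(row.pairwise_p) == {"PT-ROT", "PT-HC", "ROT-HC"}
        assert all(0 <= p <= 1 for p in row.pairwise_p.values())

    def test_planted_group_effect_detected(self):
        y, groups, cov = self._simulate(seed=3, effect=1.5)
        row = ancova_lsd(y, groups, cov)
        assert row.p_value < 1e-3
        assert row.pairwise_p["PT-ROT"] < 0.01
        assert row.pairwise_p["ROT-HC"] < 0.01
        # the null contrast is the least significant of the three
        assert row.pairwise_p["PT-HC"] > max(row.pairwise_p["PT-ROT"],
                                             row.pairwise_p["ROT-HC"])

    def test_collinear_covariate_named(self):
        y, groups, cov = self._simulate(seed=4)
        cov = cov.assign(age_copy=cov["age"] * 2.0)
        with pytest.raises(ValueError, match="age_copy"):
            ancova_lsd(y, groups, cov)

    def test_type_one_error_rate_quick(self):
        """Null ANCOVA rejections near the nominal 5% (400 replicates here;
        the full 2,000-replicate check runs in the acceptance suite)."""
        rejections = 0
        n_rep = 400
        for rep in range(n_rep):
            y, groups, cov = self._simulate(seed=10_000 + rep, effect=0.0)
            rejections += ancova_lsd(y, groups, cov).p_value < 0.05
        assert 0.02 <= rejections / n_rep <= 0.08


class TestBonferroniAndFDR:
    def test_bonferroni_examples(self):
        assert bonferroni(0.02, 3) == pytest.approx(0.06)
        assert bonferroni(0.5, 3) == 1.0

    def test_bh_step_up_worked_example(self):
        np.testing.assert_allclose(fdr_bh([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_bh_monotone(self):
        rng = np.random.default_rng(8)
        p = np.sort(rng.uniform(0, 1, 20))
        q = fdr_bh(p)
        assert np.all(np.diff(q) >= -1e-12)  # preserves p-value ordering
        assert np.all(q >= p)  # adjustment never shrinks a p-value

    def test_bh_idempotent_on_flat_adjusted_vector(self):
        # a fully tied adjusted vector is a fixed point of the step-up rule
        q = fdr_bh([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(fdr_bh(q), q, atol=1e-12)


class TestSpearman:
    def test_monotone_relationship_gives_rho_one(self):
        x = np.arange(10.0)
        res = spearman_fdr([(x, np.exp(x), ("x", "y"))])[0]
        assert res.rho == pytest.approx(1.0)

    def test_antisymmetry_under_reversal(self):
        rng = np.random.default_rng(12)
        x, y = rng.standard_normal(30), rng.standard_normal(30)
        r1 = spearman_fdr([(x, y)])[0]
        r2 = spearman_fdr([(-x, y)])[0]
        assert r1.rho == pytest.approx(-r2.rho)

    def test_constant_variable_flagged_not_tested(self):
        x = np.arange(8.0)
        results = spearman_fdr([(x, np.ones(8)), (x, x ** 2)])
        assert results[0].flagged == "constant-variable"
        assert np.isnan(results[0].rho)
        assert results[1].q_value == pytest.approx(results[1].p_value)

    def test_fdr_family_is_all_tested_pairs(self):
        rng = np.random.default_rng(14)
        pairs = [(rng.standard_normal(20), rng.standard_normal(20)) for _ in range(10)]
        results = spearman_fdr(pairs)
        qs = np.array([r.q_value for r in results])
        ps = np.array([r.p_value for r in results])
        np.testing.assert_allclose(qs, fdr_bh(ps))
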