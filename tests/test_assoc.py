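"""Association tests: worked examples, algebraic identities, null calibration."""

import numpy as np
import pytest
from scipy import stats

from epstrat import (
    DesignSample,
    anova_test,
    build_table,
    cochran_armitage,
    linear_trend_test,
    logistic_lrt,
    pearson_chisq,
    two_proportion_test,
)


def binary_sample(genotypes, groups):
    genotypes = np.asarray(genotypes, dtype=np.int64)
    groups = np.asarray(groups, dtype=np.int64)
    return DesignSample(
        design="eps",
        genotype=genotypes,
        group=groups,
        phenotype=np.zeros(len(genotypes)),
        indices=np.arange(len(genotypes)),
    )


class TestBuildTable:
    def test_codominant_tabulation(self):
        s = binary_sample([0, 1, 2, 2], [1, 1, 0, 0])
        assert np.array_equal(
            build_table(s, "codominant"), [[1, 1, 0], [0, 0, 2]]
        )

    def test_recessive_collapse(self):
        s = binary_sample([0, 1, 2, 2], [1, 1, 0, 0])
        assert np.array_equal(build_table(s, "recessive"), [[2, 0], [0, 2]])

    def test_empty_genotype_category_allowed(self):
        s = binary_sample([0, 0, 1, 1], [1, 1, 0, 0])
        table = build_table(s, "codominant")
        assert table[:, 2].sum() == 0


class TestPearsonChisq:
    def test_worked_2x2_example(self):
        res = pearson_chisq([[10, 20], [20, 10]])
        assert res.statistic == pytest.approx(20 / 3, abs=1e-10)
        assert res.p_value == pytest.approx(0.00982, abs=5e-6)
        assert res.df == 1

    def test_proportional_rows_give_zero(self):
        res = pearson_chisq([[10, 20, 30], [20, 40, 60]])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_empty_column_reduces_df(self):
        res = pearson_chisq([[10, 20, 0], [20, 10, 0]])
        assert res.df == 1 and res.valid

    def test_single_column_invalid(self):
        res = pearson_chisq([[10, 0, 0], [20, 0, 0]])
        assert not res.valid and res.reason


class TestCochranArmitage:
    def test_identical_rows_give_zero(self):
        res = cochran_armitage([[10, 10, 10], [10, 10, 10]])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_row_swap_flips_sign_only(self):
        a = cochran_armitage([[10, 10, 10], [2, 10, 18]])
        b = cochran_armitage([[2, 10, 18], [10, 10, 10]])
        assert a.statistic == pytest.approx(-b.statistic, abs=1e-12)
        assert a.p_value == pytest.approx(b.p_value, abs=1e-12)

    def test_zero_score_variance_invalid(self):
        res = cochran_armitage([[0, 10, 0], [0, 12, 0]])
        assert not res.valid

    def test_against_exhaustive_permutation_null(self):
        # Exhaustive permutation null: enumerating group relabelings is
        # equivalent to enumerating all tables with the observed margins,
        # weighted by the multivariate hypergeometric distribution.
        from math import comb

        table = np.array([[10, 10, 10], [2, 10, 18]])
        cols = table.sum(axis=0)
        n1 = table[0].sum()
        N = cols.sum()
        z_obs = cochran_armitage(table).statistic
        p_exact = 0.0
        for a in range(min(cols[0], n1) + 1):
            for b in range(min(cols[1], n1 - a) + 1):
                c = n1 - a - b
                if not 0 <= c <= cols[2]:
                    continue
                weight = (
                    comb(cols[0], a) * comb(cols[1], b) * comb(cols[2], c)
                ) / comb(N, n1)
                row0 = np.array([a, b, c])
                z = cochran_armitage(np.vstack([row0, cols - row0])).statistic
                if np.isfinite(z) and abs(z) >= abs(z_obs) - 1e-9:
                    p_exact += weight
        p_asym = cochran_armitage(table).p_value
        assert abs(p_exact - p_asym) < 0.05

    def test_equals_logistic_score_test(self):
        table = np.array([[10, 10, 10], [2, 10, 18]])
        y = np.repeat([1, 0], 30)
        x = np.concatenate([np.repeat([0, 1, 2], table[0]),
                            np.repeat([0, 1, 2], table[1])]).astype(float)
        # independently coded score test of the additive logistic term
        X = np.column_stack([np.ones_like(x), x])
        p0 = y.mean()
        score = X.T @ (y - p0)
        info = p0 * (1 - p0) * (X.T @ X)
        stat = float(score @ np.linalg.solve(info, score))
        z = cochran_armitage(table).statistic
        assert z * z == pytest.approx(stat, abs=1e-6)


def _table(genotypes, groups):
    return np.asarray(
        [np.bincount(genotypes[groups == g], minlength=3) for g in (1, 0)]
    )


class TestTwoProportion:
    def test_equal_proportions_give_zero(self):
        res = two_proportion_test([[470, 30], [470, 30]])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_worked_pooled_z(self):
        res = two_proportion_test([[470, 30], [480, 20]])
        expected = 0.02 / np.sqrt(0.05 * 0.95 * (2 / 500))
        assert res.statistic == pytest.approx(expected, abs=1e-4)
        assert res.statistic == pytest.approx(1.4510, abs=1e-4)

    def test_z_squared_equals_pearson(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            t = rng.integers(1, 100, size=(2, 2))
            z = two_proportion_test(t).statistic
            x2 = pearson_chisq(t).statistic
            assert z * z == pytest.approx(x2, abs=1e-10)
            assert two_proportion_test(t).p_value == pytest.approx(
                pearson_chisq(t).p_value, abs=1e-10
            )

    def test_degenerate_pooled_proportion(self):
        assert not two_proportion_test([[500, 0], [500, 0]]).valid


class TestAnova:
    def test_matches_hand_sums_of_squares(self):
        y = np.array([1.0, 2.0, 3.0, 2.0, 4.0, 6.0, 3.0, 6.0, 9.0])
        g = np.repeat([0, 1, 2], 3)
        res = anova_test(y, g)
        means = [y[g == k].mean() for k in range(3)]
        grand = y.mean()
        ss_between = 3 * sum((m - grand) ** 2 for m in means)
        ss_within = sum(((y[g == k] - means[k]) ** 2).sum() for k in range(3))
        f_hand = (ss_between / 2) / (ss_within / 6)
        assert res.statistic == pytest.approx(f_hand, abs=1e-10)

    def test_two_groups_f_equals_t_squared(self, rng):
        y = rng.normal(size=40)
        g = rng.integers(0, 2, size=40)
        res = anova_test(y, g)
        t = stats.ttest_ind(y[g == 0], y[g == 1]).statistic
        assert res.statistic == pytest.approx(t * t, abs=1e-10)

    def test_single_category_invalid(self):
        assert not anova_test([1.0, 2.0, 3.0], [0, 0, 0]).valid


class TestLinearTrend:
    def test_constant_genotype_invalid(self):
        assert not linear_trend_test([1.0, 2.0, 3.0], [1, 1, 1]).valid

    def test_perfectly_linear_data(self):
        res = linear_trend_test([0.0, 2.0, 4.0, 0.0, 2.0, 4.0], [0, 1, 2, 0, 1, 2])
        assert res.p_value < 1e-10

    def test_matches_normal_equations(self):
        g = np.array([0.0, 1.0, 2.0, 0.0, 1.0, 2.0])
        y = np.array([0.3, 1.8, 4.1, -0.2, 2.2, 3.9])
        res = linear_trend_test(y, g)
        X = np.column_stack([np.ones(6), g])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        se = np.sqrt(
            resid @ resid / 4 * np.linalg.inv(X.T @ X)[1, 1]
        )
        t = beta[1] / se
        assert res.statistic == pytest.approx(t, abs=1e-8)
        assert res.p_value == pytest.approx(2 * stats.t.sf(abs(t), 4), abs=1e-10)


def _hand_irls(y, X, iters=60):
    """Reference Newton-Raphson logistic fit; returns the deviance."""
    beta = np.zeros(X.shape[1])
    for _ in range(iters):
        eta = X @ beta
        p = 1 / (1 + np.exp(-eta))
        W = p * (1 - p)
        beta = beta + np.linalg.solve(X.T @ (W[:, None] * X), X.T @ (y - p))
    p = 1 / (1 + np.exp(-(X @ beta)))
    return -2 * np.sum(y * np.log(p) + (1 - y) * np.log1p(-p))


class TestLogisticLrt:
    def test_deviances_match_reference_irls(self):
        y = np.array([1, 0, 1, 1, 0, 0, 1, 0, 0, 1], dtype=float)
        g = np.array([2, 0, 1, 2, 1, 0, 1, 0, 2, 0])
        cov = np.array(
            [0.5, -1.2, 0.3, 1.8, -0.7, 0.2, -0.1, 1.1, -0.5, 0.9]
        )[:, None]
        res = logistic_lrt(y, g, cov, "additive")
        X_full = np.column_stack([np.ones(10), cov, g.astype(float)])
        X_red = np.column_stack([np.ones(10), cov])
        lr_hand = _hand_irls(y, X_red) - _hand_irls(y, X_full)
        assert res.statistic == pytest.approx(lr_hand, abs=1e-8)
        assert res.df == 1

    def test_codominant_uses_two_df(self, rng):
        y = rng.integers(0, 2, 200).astype(float)
        g = rng.integers(0, 3, 200)
        res = logistic_lrt(y, g, None, "codominant")
        assert res.df == 2 and res.valid

    def test_absent_genotype_class_reduces_df(self, rng):
        y = rng.integers(0, 2, 100).astype(float)
        g = rng.integers(0, 2, 100)  # no aa homozygotes
        res = logistic_lrt(y, g, None, "codominant")
        assert res.df == 1 and res.valid

    def test_constant_genotype_invalid(self):
        res = logistic_lrt([0, 1, 0, 1], [1, 1, 1, 1], None, "additive")
        assert not res.valid and res.reason

    def test_single_group_invalid(self):
        res = logistic_lrt([1, 1, 1, 1], [0, 1, 2, 1], None, "additive")
        assert not res.valid

    def test_balanced_null_intercept_probability_half(self, rng):
        import statsmodels.api as sm

        y = np.repeat([0.0, 1.0], 50)
        fit = sm.GLM(y, np.ones((100, 1)), family=sm.families.Binomial()).fit()
        assert 1 / (1 + np.exp(-fit.params[0])) == pytest.approx(0.5, abs=1e-9)


@pytest.mark.parametrize(
    "runner",
    [
        lambda t: cochran_armitage(t),
        lambda t: pearson_chisq(t),
    ],
    ids=["cochran_armitage", "pearson_chisq"],
)
def test_null_p_values_uniform(runner):
    """Under no confounding the p-value distribution is uniform (KS check)."""
    rng = np.random.default_rng(99)
    probs = np.array([0.36, 0.48, 0.16])
    pvals = []
    for _ in range(3000):
        t = rng.multinomial(400, probs, size=2)
        pvals.append(runner(t).p_value)
    assert stats.kstest(pvals, "uniform").pvalue > 0.001


def test_logistic_lrt_null_p_values_uniform():
    rng = np.random.default_rng(7)
    pvals = []
    for _ in range(400):
        y = rng.integers(0, 2, 300).astype(float)
        g = rng.binomial(2, 0.4, 300)
        pvals.append(logistic_lrt(y, g, None, "additive").p_value)
    assert stats.kstest(pvals, "uniform").pvalue > 0.001
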