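"""Logistic/linear model fits and the conditional + single-SNP tests."""

import numpy as np
import pytest
from scipy.optimize import minimize

from snipscan import (
    CovariateTable,
    ai_test_binary,
    ai_test_quantitative,
    fit_logistic,
    single_snp_test,
)


def optimizer_loglik(y, X):
    """Independent oracle: maximize the logistic likelihood numerically."""

    def nll(b):
        eta = X @ b
        return -np.sum(y * eta - np.logaddexp(0.0, eta))

    res = minimize(nll, np.zeros(X.shape[1]), method="BFGS",
                   options={"gtol": 1e-10})
    return -res.fun


class TestFitLogistic:
    def test_intercept_only_closed_form(self):
        y = np.array([0.0, 1.0] * 10)
        X = np.ones((20, 1))
        fit = fit_logistic(y, X)
        assert fit.converged
        assert fit.coefficients[0] == pytest.approx(0.0, abs=1e-8)
        assert fit.objective == pytest.approx(20 * np.log(0.5))

    def test_matches_optimizer_oracle_on_crafted_cells(self):
        # 9 genotype cells x case/control counts expanded to rows
        rng = np.random.default_rng(5)
        cells = [(a, b) for a in range(3) for b in range(3)]
        rows, ys = [], []
        for a, b in cells:
            n_case, n_ctrl = rng.integers(1, 15, 2)
            rows += [[1.0, a, b]] * (n_case + n_ctrl)
            ys += [1.0] * n_case + [0.0] * n_ctrl
        X, y = np.array(rows), np.array(ys)
        fit = fit_logistic(y, X)
        assert fit.converged
        assert fit.objective == pytest.approx(optimizer_loglik(y, X), abs=1e-8)

    def test_separated_data_flagged_not_converged(self):
        g = np.array([0.0] * 10 + [2.0] * 10)
        y = np.array([0.0] * 10 + [1.0] * 10)
        X = np.column_stack([np.ones(20), g])
        fit = fit_logistic(y, X)
        assert not fit.converged

    def test_collinear_column_dropped_and_flagged(self):
        rng = np.random.default_rng(0)
        g = rng.integers(0, 3, 40).astype(float)
        y = (rng.random(40) < 0.5).astype(float)
        X = np.column_stack([np.ones(40), g, 2 * g])
        fit = fit_logistic(y, X)
        assert fit.dropped == (2,)
        assert np.isnan(fit.coefficients[2])

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            fit_logistic(np.ones(5), np.ones((5, 1)))


class TestAiTestBinary:
    def test_zero_statistic_when_cells_balanced(self):
        # identical genotype distribution in cases and controls: constant
        # case:control ratio in every (x1, x2) cell -> MLE slopes 0
        cells = [(a, b) for a in range(3) for b in range(3)]
        anchor, partner, y = [], [], []
        for a, b in cells:
            anchor += [a] * 6
            partner += [b] * 6
            y += [1, 1, 0, 0, 0, 0]
        res = ai_test_binary(np.array(anchor, dtype=np.int8),
                             np.array(partner, dtype=np.int8),
                             np.array(y, dtype=float))
        assert res.status == "ok"
        assert res.statistic == pytest.approx(0.0, abs=1e-6)

    def test_statistic_is_twice_oracle_loglik_gap(self, rng):
        anchor = rng.integers(0, 3, 60).astype(np.int8)
        partner = rng.integers(0, 3, 60).astype(np.int8)
        y = (rng.random(60) < 0.4).astype(float)
        res = ai_test_binary(anchor, partner, y)
        ones = np.ones(60)
        X1 = np.column_stack([ones, anchor, partner])
        X0 = np.column_stack([ones, partner])
        expected = 2.0 * (optimizer_loglik(y, X1) - optimizer_loglik(y, X0))
        assert res.statistic == pytest.approx(max(expected, 0.0), abs=1e-6)

    def test_anchor_equal_partner_degenerate(self, rng):
        g = rng.integers(0, 3, 50).astype(np.int8)
        y = (rng.random(50) < 0.5).astype(float)
        res = ai_test_binary(g, g.copy(), y)
        assert res.status == "degenerate"
        assert np.isnan(res.p_value)

    def test_covariates_consumed_and_missing_excluded(self, rng):
        n = 120
        anchor = rng.integers(0, 3, n).astype(np.int8)
        partner = rng.integers(0, 3, n).astype(np.int8)
        y = (rng.random(n) < 0.5).astype(float)
        cov = CovariateTable(
            values=rng.normal(size=(n, 2)),
            names=["C1", "C2"],
            individual_ids=[f"i{k}" for k in range(n)],
            missing=np.array([k == 0 for k in range(n)]),
        )
        res = ai_test_binary(anchor, partner, y, cov)
        assert res.status == "ok"
        assert res.n_used == n - 1
        # adding a pure-noise covariate perturbs but does not break the test
        res0 = ai_test_binary(anchor, partner, y)
        assert np.isfinite(res.statistic) and np.isfinite(res0.statistic)

    def test_nesting_statistic_nonnegative(self, rng):
        for _ in range(25):
            n = 80
            anchor = rng.integers(0, 3, n).astype(np.int8)
            partner = np.clip(anchor + rng.integers(-1, 2, n), 0, 2).astype(np.int8)
            y = (rng.random(n) < 0.5).astype(float)
            res = ai_test_binary(anchor, partner, y)
            if res.status == "ok":
                assert res.statistic >= -1e-8


class TestAiTestQuantitative:
    def test_y_linear_in_partner_gives_f_zero(self):
        rng = np.random.default_rng(8)
        anchor = rng.integers(0, 3, 40).astype(np.int8)
        partner = rng.integers(0, 3, 40).astype(np.int8)
        y = 1.5 + 2.0 * partner
        res = ai_test_quantitative(anchor, partner, y.astype(float))
        assert res.status in ("ok", "degenerate")
        if res.status == "ok":
            assert res.statistic == pytest.approx(0.0, abs=1e-8)
            assert res.p_value == pytest.approx(1.0)

    def test_eight_individual_closed_form(self):
        anchor = np.array([0, 1, 2, 0, 1, 2, 0, 1], dtype=np.int8)
        partner = np.array([0, 0, 1, 1, 2, 2, 0, 1], dtype=np.int8)
        y = np.array([0.2, 1.1, 2.3, 0.4, 1.9, 2.8, 0.1, 1.3])
        res = ai_test_quantitative(anchor, partner, y)
        X1 = np.column_stack([np.ones(8), anchor, partner])
        X0 = np.column_stack([np.ones(8), partner])

        def rss(X):
            beta = np.linalg.solve(X.T @ X, X.T @ y)
            r = y - X @ beta
            return r @ r

        F = (rss(X0) - rss(X1)) / (rss(X1) / (8 - 3))
        assert res.statistic == pytest.approx(F, abs=1e-8)

    def test_invariant_to_individual_order(self, rng):
        n = 50
        anchor = rng.integers(0, 3, n).astype(np.int8)
        partner = rng.integers(0, 3, n).astype(np.int8)
        y = rng.normal(size=n)
        res = ai_test_quantitative(anchor, partner, y)
        perm = rng.permutation(n)
        res_p = ai_test_quantitative(anchor[perm], partner[perm], y[perm])
        assert res.statistic == pytest.approx(res_p.statistic, rel=1e-10)

    def test_too_few_individuals_degenerate(self):
        res = ai_test_quantitative(np.array([0, 1, 2], dtype=np.int8),
                                   np.array([1, 0, 2], dtype=np.int8),
                                   np.array([0.1, 0.5, 0.9]))
        assert res.status == "degenerate"


class TestSingleSnpTest:
    def test_constant_genotype_degenerate(self):
        stat, p = single_snp_test(np.ones(10, dtype=np.int8),
                                  np.array([0.0, 1.0] * 5))
        assert np.isnan(stat) and np.isnan(p)

    def test_matches_oracle_under_independence(self, rng):
        n = 400
        g = rng.integers(0, 3, n).astype(np.int8)
        y = (rng.random(n) < 0.5).astype(float)
        stat, p = single_snp_test(g, y)
        ones = np.ones(n)
        expected = 2.0 * (
            optimizer_loglik(y, np.column_stack([ones, g]))
            - optimizer_loglik(y, ones[:, None])
        )
        assert stat == pytest.approx(max(expected, 0.0), abs=1e-6)
        assert stat < 15.0  # no association: statistic should be small

    def test_quantitative_branch_autodetected(self, rng):
        n = 60
        g = rng.integers(0, 3, n).astype(np.int8)
        y = 0.5 * g + rng.normal(size=n)
        stat, p = single_snp_test(g, y)
        assert np.isfinite(stat) and 0.0 < p <= 1.0
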