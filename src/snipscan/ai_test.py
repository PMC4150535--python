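"""Conditional (artificial-imputation) and single-SNP association tests.

Binary traits use logistic regression: the AI statistic is the 1-df
likelihood-ratio test of

    logit P(case) = b0 + b1*x1 + b2*x2 (+ covariates)   vs. the same without x1,

where x1 and x2 are the minor-allele dosages at the anchor and partner SNPs
(an additive allelic model on the log-odds scale, i.e. multiplicative odds
between and within loci — the only coding offered, since dominant/recessive
codings lose power when LD with the causal variant is weak).  Quantitative
traits use the analogous nested ordinary-least-squares models compared by a
1-df F test, F = (RSS0 - RSS1) / (RSS1 / (n - 3 - c)).

Missing-data policy is complete-case per test: an individual is dropped from
one anchor's test if its phenotype, either genotype, or any covariate is
missing, so n may differ between anchors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit
from scipy.stats import chi2, f as f_dist

from .genotype_io import MISSING, CovariateTable

__all__ = [
    "RegressionFit",
    "AITestResult",
    "fit_logistic",
    "ai_test_binary",
    "ai_test_quantitative",
    "single_snp_test",
]

_MAX_ITER = 50
_GRAD_TOL = 1e-8
_LL_TOL = 1e-10


@dataclass
class RegressionFit:
    """A maximized regression model: coefficients plus fit diagnostics.

    ``objective`` is the maximized log-likelihood for logistic fits and the
    residual sum of squares for linear fits.  ``dropped`` lists design
    columns removed for collinearity (their coefficients are NaN).
    """

    coefficients: np.ndarray
    objective: float
    converged: bool
    n_used: int
    dropped: tuple[int, ...] = ()


@dataclass
class AITestResult:
    """AI (anchor | partner) test plus the companion single-SNP test."""

    anchor_id: str
    partner_id: str | None
    statistic: float
    df: int
    p_value: float
    test_type: str  # "logistic_LRT" | "linear_F"
    single_snp_statistic: float
    single_snp_p: float
    status: str  # "ok" | "no_partner" | "not_converged" | "degenerate"
    n_used: int = 0


# ---------------------------------------------------------------------------
# model fitting
# ---------------------------------------------------------------------------

def _independent_columns(X: np.ndarray, tol: float = 1e-9) -> list[int]:
    """Left-to-right greedy column selection: earlier columns win ties.

    Modified Gram-Schmidt; a column is dropped when its residual norm after
    projection on the kept columns falls below ``tol`` times its own norm.
    """
    n, p = X.shape
    keep: list[int] = []
    basis: list[np.ndarray] = []
    for j in range(p):
        v = X[:, j].astype(float)
        norm0 = np.linalg.norm(v)
        if norm0 == 0.0:
            continue
        for q in basis:
            v = v - (q @ v) * q
        if np.linalg.norm(v) > tol * max(norm0, 1.0) * max(n, p):
            basis.append(v / np.linalg.norm(v))
            keep.append(j)
    return keep


def fit_logistic(y: np.ndarray, X: np.ndarray,
                 weights: np.ndarray | None = None) -> RegressionFit:
    """Maximum-likelihood logistic regression by Newton/IRLS.

    ``y`` holds 0/1 outcomes; ``X`` must include an intercept column.
    Optional non-negative ``weights`` are frequency weights.  Convergence:
    max |score| < 1e-8 or relative log-likelihood change < 1e-10, at most 50
    iterations; complete separation therefore surfaces as
    ``converged=False``.  Collinear columns are dropped and flagged, their
    coefficients set to NaN.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)
    n, p = X.shape
    if len(y) != n:
        raise ValueError("y and X have inconsistent lengths")
    if not (np.all((y == 0) | (y == 1))):
        raise ValueError("y must be 0/1")
    if y.min() == y.max():
        raise ValueError("y has a single class")

    keep = _independent_columns(X)
    dropped = tuple(j for j in range(p) if j not in keep)
    Xk = X[:, keep]
    beta = np.zeros(len(keep))

    def loglik(eta: np.ndarray) -> float:
        return float(np.sum(w * (y * eta - np.logaddexp(0.0, eta))))

    eta = Xk @ beta
    ll = loglik(eta)
    converged = False
    for _ in range(_MAX_ITER):
        mu = expit(np.clip(eta, -30, 30))
        grad = Xk.T @ (w * (y - mu))
        wt = w * mu * (1.0 - mu)
        H = Xk.T @ (Xk * wt[:, None])
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            H[np.diag_indices_from(H)] += 1e-8
            step = np.linalg.solve(H, grad)
        new_beta = beta + step
        new_ll = loglik(Xk @ new_beta)
        halvings = 0
        while new_ll < ll - 1e-12 and halvings < 25:
            step *= 0.5
            new_beta = beta + step
            new_ll = loglik(Xk @ new_beta)
            halvings += 1
        beta = new_beta
        eta = Xk @ beta
        if np.max(np.abs(grad)) < _GRAD_TOL or (
            abs(new_ll - ll) < _LL_TOL * (abs(ll) + 1.0)
        ):
            ll = new_ll
            converged = True
            break
        ll = new_ll

    # complete separation: every observation perfectly classified, so the
    # MLE diverges even though the log-likelihood has plateaued near 0
    mu = expit(np.clip(eta, -30, 30))
    if converged and np.all(np.where(y == 1, mu > 1 - 1e-6, mu < 1e-6)):
        converged = False

    coef = np.full(p, np.nan)
    coef[keep] = beta
    return RegressionFit(coef, ll, converged, n, dropped)


def _ols_rss(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, float, int]:
    """Least-squares fit; returns (coefficients, RSS, rank)."""
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return coef, float(resid @ resid), int(rank)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _complete_mask(y, covariates, *dosages) -> np.ndarray:
    ok = np.isfinite(np.asarray(y, dtype=float))
    for g in dosages:
        ok &= np.asarray(g) != MISSING
    if covariates is not None and covariates.n_covariates >= 0:
        ok &= ~covariates.missing
        if covariates.n_covariates:
            ok &= np.all(np.isfinite(covariates.values), axis=1)
    return ok


def _cov_block(covariates: CovariateTable | None, mask: np.ndarray) -> np.ndarray:
    if covariates is None or covariates.n_covariates == 0:
        return np.empty((int(mask.sum()), 0))
    return covariates.values[mask]


def _na_result(anchor_id, partner_id, test_type, status, n_used=0) -> AITestResult:
    return AITestResult(anchor_id, partner_id, np.nan, 1, np.nan, test_type,
                        np.nan, np.nan, status, n_used)


# ---------------------------------------------------------------------------
# tests
# ---------------------------------------------------------------------------

def ai_test_binary(
    anchor: np.ndarray,
    partner: np.ndarray,
    y: np.ndarray,
    covariates: CovariateTable | None = None,
    anchor_id: str = "anchor",
    partner_id: str = "partner",
) -> AITestResult:
    """1-df logistic LRT of the anchor SNP conditional on the partner SNP.

    Also reports the companion single-SNP LRT of the anchor against the
    covariate-only null on the same complete cases.
    """
    mask = _complete_mask(y, covariates, anchor, partner)
    n = int(mask.sum())
    a = np.asarray(anchor, dtype=float)[mask]
    b = np.asarray(partner, dtype=float)[mask]
    yy = np.asarray(y, dtype=float)[mask]
    if n == 0 or yy.min() == yy.max():
        return _na_result(anchor_id, partner_id, "logistic_LRT", "degenerate", n)
    if a.min() == a.max() or b.min() == b.max():
        return _na_result(anchor_id, partner_id, "logistic_LRT", "degenerate", n)
    C = _cov_block(covariates, mask)
    ones = np.ones((n, 1))
    X_full = np.hstack([ones, a[:, None], b[:, None], C])
    X_null = np.hstack([ones, b[:, None], C])
    fit1 = fit_logistic(yy, X_full)
    if any(j in fit1.dropped for j in (1, 2)):
        # anchor and partner collinear (or collinear with covariates): the
        # two-SNP model is unidentifiable
        return _na_result(anchor_id, partner_id, "logistic_LRT", "degenerate", n)
    fit0 = fit_logistic(yy, X_null)
    if not (fit1.converged and fit0.converged):
        return _na_result(anchor_id, partner_id, "logistic_LRT", "not_converged", n)
    stat = max(2.0 * (fit1.objective - fit0.objective), 0.0)
    p = float(chi2.sf(stat, 1))

    X_single = np.hstack([ones, a[:, None], C])
    X_base = np.hstack([ones, C])
    fs1 = fit_logistic(yy, X_single)
    fs0 = fit_logistic(yy, X_base)
    if fs1.converged and fs0.converged:
        s_stat = max(2.0 * (fs1.objective - fs0.objective), 0.0)
        s_p = float(chi2.sf(s_stat, 1))
    else:
        s_stat, s_p = np.nan, np.nan
    return AITestResult(anchor_id, partner_id, stat, 1, p, "logistic_LRT",
                        s_stat, s_p, "ok", n)


def ai_test_quantitative(
    anchor: np.ndarray,
    partner: np.ndarray,
    y: np.ndarray,
    covariates: CovariateTable | None = None,
    anchor_id: str = "anchor",
    partner_id: str = "partner",
) -> AITestResult:
    """1-df F test of the anchor SNP conditional on the partner SNP (OLS)."""
    mask = _complete_mask(y, covariates, anchor, partner)
    n = int(mask.sum())
    a = np.asarray(anchor, dtype=float)[mask]
    b = np.asarray(partner, dtype=float)[mask]
    yy = np.asarray(y, dtype=float)[mask]
    C = _cov_block(covariates, mask)
    c = C.shape[1]
    df_denom = n - 3 - c
    if n == 0 or yy.min() == yy.max() or df_denom < 1:
        return _na_result(anchor_id, partner_id, "linear_F", "degenerate", n)
    if a.min() == a.max() or b.min() == b.max():
        return _na_result(anchor_id, partner_id, "linear_F", "degenerate", n)
    ones = np.ones((n, 1))
    X_full = np.hstack([ones, a[:, None], b[:, None], C])
    X_null = np.hstack([ones, b[:, None], C])
    if len(_independent_columns(X_full)) < X_full.shape[1]:
        return _na_result(anchor_id, partner_id, "linear_F", "degenerate", n)
    _, rss1, _ = _ols_rss(yy, X_full)
    _, rss0, _ = _ols_rss(yy, X_null)
    scale = float(yy @ yy) + 1.0
    if rss1 <= 1e-12 * scale:
        # (near-)perfect fit: F is 0 when the null already fits perfectly,
        # otherwise the statistic is unbounded and the test degenerate
        if rss0 - rss1 <= 1e-12 * scale:
            return AITestResult(anchor_id, partner_id, 0.0, 1, 1.0,
                                "linear_F", np.nan, np.nan, "ok", n)
        return _na_result(anchor_id, partner_id, "linear_F", "degenerate", n)
    F = max(rss0 - rss1, 0.0) / (rss1 / df_denom)
    p = float(f_dist.sf(F, 1, df_denom))

    X_single = np.hstack([ones, a[:, None], C])
    X_base = np.hstack([ones, C])
    _, srss1, _ = _ols_rss(yy, X_single)
    _, srss0, _ = _ols_rss(yy, X_base)
    sdf = n - 2 - c
    if srss1 > 0.0 and sdf >= 1:
        sF = max(srss0 - srss1, 0.0) / (srss1 / sdf)
        s_p = float(f_dist.sf(sF, 1, sdf))
    else:
        sF, s_p = np.nan, np.nan
    return AITestResult(anchor_id, partner_id, float(F), 1, p, "linear_F",
                        sF, s_p, "ok", n)


def single_snp_test(
    g: np.ndarray,
    y: np.ndarray,
    covariates: CovariateTable | None = None,
    binary: bool | None = None,
) -> tuple[float, float]:
    """1-df test of one SNP against the covariate-only null.

    Logistic LRT for binary phenotypes, F test for quantitative ones
    (auto-detected from the values of ``y`` unless ``binary`` is given).
    Returns ``(statistic, p_value)``; NaNs for degenerate input.
    """
    mask = _complete_mask(y, covariates, g)
    n = int(mask.sum())
    gg = np.asarray(g, dtype=float)[mask]
    yy = np.asarray(y, dtype=float)[mask]
    if n == 0 or gg.min() == gg.max() or yy.min() == yy.max():
        return np.nan, np.nan
    if binary is None:
        binary = bool(np.all((yy == 0) | (yy == 1)))
    C = _cov_block(covariates, mask)
    ones = np.ones((n, 1))
    X1 = np.hstack([ones, gg[:, None], C])
    X0 = np.hstack([ones, C])
    if binary:
        f1 = fit_logistic(yy, X1)
        f0 = fit_logistic(yy, X0)
        if not (f1.converged and f0.converged) or 1 in f1.dropped:
            return np.nan, np.nan
        stat = max(2.0 * (f1.objective - f0.objective), 0.0)
        return stat, float(chi2.sf(stat, 1))
    c = C.shape[1]
    df_denom = n - 2 - c
    if df_denom < 1:
        return np.nan, np.nan
    _, rss1, _ = _ols_rss(yy, X1)
    _, rss0, _ = _ols_rss(yy, X0)
    if rss1 <= 0.0:
        return np.nan, np.nan
    F = max(rss0 - rss1, 0.0) / (rss1 / df_denom)
    return float(F), float(f_dist.sf(F, 1, df_denom))
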