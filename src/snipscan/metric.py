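"""Anchor-partner correlation and the simulation-derived partner-score metric.

The partner-selection score maps the anchor-partner genotype correlation
(squared Pearson r² of minor-allele dosages) to a usefulness score in
[0, 100].  The map is built empirically: haplotype frequencies at three loci
(anchor, unobserved causal, partner) are sampled from the full frequency
simplex, case/control panels are simulated under a penetrance model, and for
each replicate the difference between the conditional (anchor-given-partner)
likelihood-ratio statistic and the plain single-SNP statistic is recorded.
Correlations whose replicates land in the top 1% of those differences most
often get the highest scores.  Intuitively the curve peaks at intermediate
r²: a partner too correlated with the anchor adds nothing beyond the anchor,
one too uncorrelated adds nothing to condition on.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import expit

from .genotype_io import MISSING

__all__ = [
    "UNDEFINED",
    "HaplotypeDiseaseModel",
    "MetricConstructionConfig",
    "MetricCurve",
    "genotype_r2",
    "haplotype_r2_from_counts",
    "sample_haplotype_partition",
    "simulate_case_control",
    "run_metric_construction",
    "score",
    "default_curve",
    "MODEL_PENETRANCES",
]

#: Returned by :func:`genotype_r2` when the correlation does not exist
#: (a constant vector or fewer than two complete pairs).
UNDEFINED = None

#: Construction penetrances per causal-model label: P(disease | 0/1/2 copies
#: of the causal allele).  The multiplicative set doubles the odds-scale
#: effect per allele (0.01, 0.015, 0.0225).
MODEL_PENETRANCES: dict[str, tuple[float, float, float]] = {
    "multiplicative": (0.01, 0.015, 0.0225),
    "dominant": (0.01, 0.0225, 0.0225),
    "recessive": (0.01, 0.01, 0.0225),
}


# ---------------------------------------------------------------------------
# correlation
# ---------------------------------------------------------------------------

def genotype_r2(g1: np.ndarray, g2: np.ndarray):
    """Squared Pearson correlation of two dosage vectors.

    Pairs with a missing entry in either vector are dropped (pairwise
    complete).  Returns :data:`UNDEFINED` if fewer than two complete pairs
    remain or either vector is constant on them.
    """
    g1 = np.asarray(g1)
    g2 = np.asarray(g2)
    if g1.shape != g2.shape:
        raise ValueError("dosage vectors must have the same length")
    ok = (g1 != MISSING) & (g2 != MISSING)
    x = g1[ok].astype(float)
    y = g2[ok].astype(float)
    if x.size < 2:
        return UNDEFINED
    x -= x.mean()
    y -= y.mean()
    vx = x @ x
    vy = y @ y
    if vx == 0.0 or vy == 0.0:
        return UNDEFINED
    c = x @ y
    return float(c * c / (vx * vy))


def haplotype_r2_from_counts(
    counts: np.ndarray, x_values: np.ndarray, y_values: np.ndarray
) -> float | None:
    """Squared Pearson correlation under a discrete haplotype distribution.

    ``counts`` are non-negative haplotype weights (expected counts or
    frequencies); ``x_values``/``y_values`` assign a number to each haplotype
    (e.g. allele indicators).  Returns :data:`UNDEFINED` on zero variance.
    """
    w = np.asarray(counts, dtype=float)
    x = np.asarray(x_values, dtype=float)
    y = np.asarray(y_values, dtype=float)
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("counts must be non-negative and not all zero")
    w = w / w.sum()
    mx = w @ x
    my = w @ y
    vx = w @ (x - mx) ** 2
    vy = w @ (y - my) ** 2
    if vx == 0.0 or vy == 0.0:
        return UNDEFINED
    cov = w @ ((x - mx) * (y - my))
    return float(cov * cov / (vx * vy))


# ---------------------------------------------------------------------------
# haplotype-frequency partition sampler
# ---------------------------------------------------------------------------

def sample_haplotype_partition(
    rng: np.random.Generator, size: int | None = None, return_order: bool = False
):
    """Draw haplotype-frequency vectors by sequential uniform stick-breaking.

    One draw assigns the 8 haplotype frequencies in a uniformly random order:
    each frequency in turn is uniform on [0, 1 - S] where S is the sum already
    assigned, and the last haplotype takes the remainder.  With ``size`` a
    ``(size, 8)`` array is returned; ``return_order`` additionally yields the
    assignment order (indices of haplotypes in the order they were drawn).
    """
    squeeze = size is None
    r = 1 if squeeze else int(size)
    order = np.argsort(rng.random((r, 8)), axis=1)  # uniform random permutation
    u = rng.random((r, 7))
    freqs_in_order = np.empty((r, 8))
    remaining = np.ones(r)
    for k in range(7):
        f = u[:, k] * remaining
        freqs_in_order[:, k] = f
        remaining -= f
    freqs_in_order[:, 7] = remaining
    out = np.empty((r, 8))
    np.put_along_axis(out, order, freqs_in_order, axis=1)
    if squeeze:
        out = out[0]
        order = order[0]
    if return_order:
        return out, order
    return out


# ---------------------------------------------------------------------------
# three-SNP disease model and exact conditional case/control simulation
# ---------------------------------------------------------------------------

# Haplotype index h = 4*a + 2*d + 1*p over (anchor, disease, partner) alleles,
# 1 denoting the counted (causal/minor) allele at each locus.
_HAP_ALLELES = np.array(
    [[(h >> 2) & 1, (h >> 1) & 1, h & 1] for h in range(8)], dtype=np.int64
)

# Map the 64 ordered haplotype pairs to the 27 genotype triples
# (anchor, disease, partner dosages), each in {0,1,2}.
_PAIR_TRIPLE = (
    _HAP_ALLELES[:, None, :] + _HAP_ALLELES[None, :, :]
).reshape(64, 3)
_TRIPLE_INDEX = _PAIR_TRIPLE @ np.array([9, 3, 1])  # 0..26
_M_PAIR_TO_TRIPLE = np.zeros((27, 64))
_M_PAIR_TO_TRIPLE[_TRIPLE_INDEX, np.arange(64)] = 1.0

_TRIPLES = np.array([[a, d, p] for a in range(3) for d in range(3) for p in range(3)])
_CELL_OF_TRIPLE = _TRIPLES[:, 0] * 3 + _TRIPLES[:, 2]  # (anchor, partner) cell 0..8
_M_TRIPLE_TO_CELL = np.zeros((9, 27))
_M_TRIPLE_TO_CELL[_CELL_OF_TRIPLE, np.arange(27)] = 1.0

#: Dosage coordinates (anchor, partner) of the 9 contingency cells.
CELL_DOSAGES = np.array([[a, p] for a in range(3) for p in range(3)], dtype=float)


@dataclass(frozen=True)
class HaplotypeDiseaseModel:
    """Eight (anchor, disease, partner) haplotype frequencies + penetrances.

    ``penetrances[k]`` is P(disease | k copies of the causal allele).
    """

    hap_freqs: np.ndarray
    penetrances: tuple[float, float, float]

    def __post_init__(self) -> None:
        f = np.asarray(self.hap_freqs, dtype=float)
        if f.shape != (8,):
            raise ValueError("hap_freqs must have 8 entries")
        if np.any(f < 0) or abs(f.sum() - 1.0) > 1e-12:
            raise ValueError("hap_freqs must be non-negative and sum to 1")
        if not all(0.0 <= p <= 1.0 for p in self.penetrances):
            raise ValueError("penetrances must lie in [0, 1]")
        object.__setattr__(self, "hap_freqs", f)

    def triple_probabilities(self) -> np.ndarray:
        """P(genotype triple) under random mating, shape (27,)."""
        pair = np.outer(self.hap_freqs, self.hap_freqs).ravel()
        return _M_PAIR_TO_TRIPLE @ pair

    def conditional_cell_distributions(self) -> tuple[np.ndarray, np.ndarray, float]:
        """(case, control) distributions over the 9 (anchor, partner) cells.

        Marginalizes the unobserved causal genotype.  Also returns the disease
        prevalence.  Raises for a degenerate model (prevalence 0 or 1).
        """
        p27 = self.triple_probabilities()
        pen = np.asarray(self.penetrances)[_TRIPLES[:, 1]]
        case27 = p27 * pen
        ctrl27 = p27 * (1.0 - pen)
        prevalence = case27.sum()
        if prevalence <= 0.0 or prevalence >= 1.0:
            raise ValueError("degenerate disease model: prevalence is 0 or 1")
        case9 = _M_TRIPLE_TO_CELL @ case27 / prevalence
        ctrl9 = _M_TRIPLE_TO_CELL @ ctrl27 / (1.0 - prevalence)
        return case9, ctrl9, float(prevalence)


def simulate_case_control(
    model: HaplotypeDiseaseModel,
    n_cases: int,
    n_controls: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate genotypes at (anchor, disease, partner) for a case/control panel.

    Individuals are pairs of independent haplotype draws; disease follows the
    penetrance of the causal-allele count.  Sampling is from the exact
    conditional triple distributions given status, so exactly ``n_cases``
    cases then ``n_controls`` controls are returned.

    Returns ``(genotypes, phenotype)`` with genotypes of shape
    ``(n_cases + n_controls, 3)`` (dosages) and phenotype 1 = case.
    """
    p27 = model.triple_probabilities()
    pen = np.asarray(model.penetrances)[_TRIPLES[:, 1]]
    case27 = p27 * pen
    ctrl27 = p27 * (1.0 - pen)
    prevalence = case27.sum()
    if prevalence <= 0.0 or prevalence >= 1.0:
        raise ValueError("degenerate disease model: prevalence is 0 or 1")
    case27 /= prevalence
    ctrl27 /= 1.0 - prevalence
    idx_case = rng.choice(27, size=n_cases, p=case27)
    idx_ctrl = rng.choice(27, size=n_controls, p=ctrl27)
    geno = _TRIPLES[np.concatenate([idx_case, idx_ctrl])]
    pheno = np.concatenate([np.ones(n_cases), np.zeros(n_controls)])
    return geno.astype(np.int8), pheno


# ---------------------------------------------------------------------------
# batched weighted logistic regression on the 9-cell contingency table
# ---------------------------------------------------------------------------

def _batched_logistic_ll(
    X: np.ndarray,
    successes: np.ndarray,
    totals: np.ndarray,
    max_iter: int = 50,
    grad_tol: float = 1e-8,
    ll_tol: float = 1e-10,
) -> np.ndarray:
    """Maximized binomial log-likelihoods for many small logistic models.

    ``X`` is the shared (cells, p) design; ``successes``/``totals`` are
    (replicates, cells) case counts and cell totals.  Returns (replicates,)
    maximized log-likelihoods (binomial coefficients omitted — they cancel in
    likelihood ratios on the same data).  Newton iterations with a ridge
    fallback; near-separated replicates are bounded by clipping the linear
    predictor at +/-30.
    """
    R, C = successes.shape
    p = X.shape[1]
    beta = np.zeros((R, p))
    s = successes.astype(float)
    n = totals.astype(float)

    def loglik(eta, s_, n_):
        # s*eta - n*log(1+e^eta), stable via logaddexp
        return np.sum(s_ * eta - n_ * np.logaddexp(0.0, eta), axis=1)

    eta = np.clip(beta @ X.T, -30, 30)
    ll = loglik(eta, s, n)
    active = np.ones(R, dtype=bool)
    for _ in range(max_iter):
        if not active.any():
            break
        a = np.nonzero(active)[0]
        eta_a = np.clip(beta[a] @ X.T, -30, 30)
        mu = expit(eta_a)
        grad = (s[a] - n[a] * mu) @ X  # (ra, p)
        w = n[a] * mu * (1.0 - mu)
        H = np.einsum("rc,cp,cq->rpq", w, X, X)
        H[:, np.arange(p), np.arange(p)] += 1e-10
        try:
            step = np.linalg.solve(H, grad[..., None])[..., 0]
        except np.linalg.LinAlgError:
            H[:, np.arange(p), np.arange(p)] += 1e-6
            step = np.linalg.solve(H, grad[..., None])[..., 0]
        # step-halving to guarantee monotone log-likelihood
        new_beta = beta[a] + step
        new_ll = loglik(np.clip(new_beta @ X.T, -30, 30), s[a], n[a])
        bad = new_ll < ll[a]
        for _h in range(20):
            if not bad.any():
                break
            step[bad] *= 0.5
            new_beta[bad] = beta[a][bad] + step[bad]
            new_ll[bad] = loglik(np.clip(new_beta[bad] @ X.T, -30, 30),
                                 s[a][bad], n[a][bad])
            bad = new_ll < ll[a] - 1e-12
        improved = np.abs(new_ll - ll[a])
        beta[a] = new_beta
        done = (np.max(np.abs(grad), axis=1) < grad_tol) | (
            improved < ll_tol * (np.abs(ll[a]) + 1.0)
        )
        ll[a] = new_ll
        active[a[done]] = False
    return ll


def _intercept_only_ll(successes: np.ndarray, totals: np.ndarray) -> np.ndarray:
    s = successes.sum(axis=1).astype(float)
    n = totals.sum(axis=1).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = s / n
        ll = s * np.log(p) + (n - s) * np.log1p(-p)
    return np.where((s == 0) | (s == n), 0.0, np.nan_to_num(ll))


def _weighted_r2_cells(totals: np.ndarray) -> np.ndarray:
    """All-sample anchor-partner r² from 9-cell totals; NaN if monomorphic."""
    w = totals.astype(float)
    n = w.sum(axis=1, keepdims=True)
    p = w / n
    x1 = CELL_DOSAGES[:, 0]
    x2 = CELL_DOSAGES[:, 1]
    m1 = p @ x1
    m2 = p @ x2
    v1 = p @ (x1 ** 2) - m1 ** 2
    v2 = p @ (x2 ** 2) - m2 ** 2
    cov = p @ (x1 * x2) - m1 * m2
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = cov ** 2 / (v1 * v2)
    r2[(v1 <= 0) | (v2 <= 0)] = np.nan
    return r2


# ---------------------------------------------------------------------------
# metric construction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MetricConstructionConfig:
    """Parameters of the score-curve construction simulation."""

    n_replicates: int = 1_000_000
    n_cases: int = 1_000
    n_controls: int = 1_000
    penetrances: tuple[float, float, float] = MODEL_PENETRANCES["multiplicative"]
    top_fraction: float = 0.01
    bin_width: float = 0.05
    poly_degree: int = 5
    n_tail_bins_excluded: int = 3
    seed: int = 1
    model_label: str = "multiplicative"

    def __post_init__(self) -> None:
        if not (0.0 < self.top_fraction < 1.0):
            raise ValueError("top_fraction must be in (0, 1)")
        n_bins = round(1.0 / self.bin_width)
        if abs(n_bins * self.bin_width - 1.0) > 1e-12:
            raise ValueError("bin_width must divide (0, 1] into equal bins")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


@dataclass
class MetricCurve:
    """Piecewise score curve mapping anchor-partner r² to [0, 100].

    A degree-``poly_degree`` polynomial covers the central bins; the excluded
    low/high tail bins are covered by straight segments through the boundary
    anchor points (0,0) and (1,0).  The whole curve is clamped at 0 and scaled
    so its grid maximum is 100.
    """

    model_label: str
    poly_coeffs: np.ndarray      # ascending powers
    tail_lo_x: float             # core region is [tail_lo_x, tail_hi_x]
    tail_hi_x: float
    tail_lo_y: float             # raw curve value at the core boundaries
    tail_hi_y: float
    scale: float
    config: dict = field(default_factory=dict)
    bin_table: dict = field(default_factory=dict)

    def _raw(self, r2: np.ndarray) -> np.ndarray:
        r2 = np.asarray(r2, dtype=float)
        core = np.polynomial.polynomial.polyval(r2, self.poly_coeffs)
        out = np.where(r2 < self.tail_lo_x,
                       _line(r2, 0.0, 0.0, self.tail_lo_x, self.tail_lo_y),
                       core)
        out = np.where(r2 > self.tail_hi_x,
                       _line(r2, self.tail_hi_x, self.tail_hi_y, 1.0, 0.0),
                       out)
        return np.clip(out, 0.0, None)

    def evaluate(self, r2) -> np.ndarray:
        """Score(s) in [0, 100] for r² value(s) in [0, 1]."""
        return np.clip(self._raw(np.asarray(r2, dtype=float)) * self.scale,
                       0.0, 100.0)

    def argmax(self, grid_step: float = 1e-3) -> float:
        grid = np.arange(0.0, 1.0 + grid_step / 2, grid_step)
        return float(grid[np.argmax(self.evaluate(grid))])

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "model_label": self.model_label,
            "poly_coeffs": list(map(float, self.poly_coeffs)),
            "tail_lo_x": self.tail_lo_x, "tail_hi_x": self.tail_hi_x,
            "tail_lo_y": self.tail_lo_y, "tail_hi_y": self.tail_hi_y,
            "scale": self.scale,
            "config": self.config,
            "bin_table": self.bin_table,
        }

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_dict(cls, d: dict) -> "MetricCurve":
        return cls(
            model_label=d["model_label"],
            poly_coeffs=np.asarray(d["poly_coeffs"], dtype=float),
            tail_lo_x=d["tail_lo_x"], tail_hi_x=d["tail_hi_x"],
            tail_lo_y=d["tail_lo_y"], tail_hi_y=d["tail_hi_y"],
            scale=d["scale"],
            config=d.get("config", {}),
            bin_table=d.get("bin_table", {}),
        )

    @classmethod
    def load(cls, path) -> "MetricCurve":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _line(x, x0, y0, x1, y1):
    return y0 + (np.asarray(x, dtype=float) - x0) * (y1 - y0) / (x1 - x0)


_X_FULL = np.column_stack([np.ones(9), CELL_DOSAGES])          # 1 + anchor + partner
_X_PARTNER = np.column_stack([np.ones(9), CELL_DOSAGES[:, 1]])  # 1 + partner
_X_ANCHOR = np.column_stack([np.ones(9), CELL_DOSAGES[:, 0]])   # 1 + anchor


def _simulate_replicate_statistics(
    config: MetricConstructionConfig,
    rng: np.random.Generator,
    chunk: int = 50_000,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-replicate (r², AI − single-SNP statistic difference).

    Replicates with a monomorphic anchor or partner in the sampled panel are
    dropped.  Likelihoods are evaluated on the 9-cell (anchor x partner
    dosage) x status contingency table — identical to per-individual fits.
    """
    pen_by_triple = np.asarray(config.penetrances)[_TRIPLES[:, 1]]
    r2_out: list[np.ndarray] = []
    diff_out: list[np.ndarray] = []
    remaining = config.n_replicates
    while remaining > 0:
        r = min(chunk, remaining)
        remaining -= r
        freqs = sample_haplotype_partition(rng, size=r)          # (r, 8)
        pair = np.einsum("ri,rj->rij", freqs, freqs).reshape(r, 64)
        p27 = pair @ _M_PAIR_TO_TRIPLE.T                          # (r, 27)
        case27 = p27 * pen_by_triple
        ctrl27 = p27 * (1.0 - pen_by_triple)
        prev = case27.sum(axis=1)
        ok = (prev > 0.0) & (prev < 1.0)
        case27 = case27[ok] / prev[ok, None]
        ctrl27 = ctrl27[ok] / (1.0 - prev[ok, None])
        case9 = case27 @ _M_TRIPLE_TO_CELL.T
        ctrl9 = ctrl27 @ _M_TRIPLE_TO_CELL.T
        # guard tiny negative round-off before multinomial sampling
        case9 = np.clip(case9, 0.0, None)
        case9 /= case9.sum(axis=1, keepdims=True)
        ctrl9 = np.clip(ctrl9, 0.0, None)
        ctrl9 /= ctrl9.sum(axis=1, keepdims=True)
        s = rng.multinomial(config.n_cases, case9)               # case counts
        c = rng.multinomial(config.n_controls, ctrl9)
        totals = s + c
        r2 = _weighted_r2_cells(totals)
        keep = np.isfinite(r2)
        s, c, totals, r2 = s[keep], c[keep], totals[keep], r2[keep]
        if r2.size == 0:
            continue
        ll_full = _batched_logistic_ll(_X_FULL, s, totals)
        ll_partner = _batched_logistic_ll(_X_PARTNER, s, totals)
        ll_anchor = _batched_logistic_ll(_X_ANCHOR, s, totals)
        ll_null = _intercept_only_ll(s, totals)
        ai = 2.0 * (ll_full - ll_partner)
        single = 2.0 * (ll_anchor - ll_null)
        r2_out.append(r2)
        diff_out.append(ai - single)
    return np.concatenate(r2_out), np.concatenate(diff_out)


def run_metric_construction(
    config: MetricConstructionConfig,
    rng: np.random.Generator | None = None,
) -> MetricCurve:
    """Build a :class:`MetricCurve` by the full construction simulation.

    For each replicate: sample 8 haplotype frequencies, simulate the
    case/control panel, record the all-sample anchor-partner r² and the
    difference (conditional AI statistic) − (single-SNP statistic).  The top
    ``top_fraction`` of differences is flagged; per r²-bin top probabilities
    are fitted by a degree-``poly_degree`` polynomial anchored at (0,0) and
    (1,0), with the excluded tail bins covered by linear segments; the curve
    is scaled to a maximum of 100.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    r2, diff = _simulate_replicate_statistics(config, rng)

    threshold = np.quantile(diff, 1.0 - config.top_fraction)
    top = diff >= threshold

    n_bins = round(1.0 / config.bin_width)
    bin_idx = np.minimum((r2 / config.bin_width).astype(int), n_bins - 1)
    counts = np.bincount(bin_idx, minlength=n_bins)
    tops = np.bincount(bin_idx, weights=top.astype(float), minlength=n_bins)
    populated = np.nonzero(counts > 0)[0]
    mids = (populated + 0.5) * config.bin_width
    probs = tops[populated] / counts[populated]

    k = config.n_tail_bins_excluded
    if len(populated) <= 2 * k + config.poly_degree:
        raise ValueError(
            f"only {len(populated)} populated bins; too few for the fit "
            f"(need > {2 * k + config.poly_degree})"
        )
    core = slice(k, len(populated) - k)
    fit_x = np.concatenate([[0.0], mids[core], [1.0]])
    fit_y = np.concatenate([[0.0], probs[core], [0.0]])
    coeffs = np.polynomial.polynomial.polyfit(fit_x, fit_y, config.poly_degree)

    curve = MetricCurve(
        model_label=config.model_label,
        poly_coeffs=coeffs,
        tail_lo_x=float(mids[core][0]),
        tail_hi_x=float(mids[core][-1]),
        tail_lo_y=float(probs[core][0]),
        tail_hi_y=float(probs[core][-1]),
        scale=1.0,
        config={
            "n_replicates": config.n_replicates,
            "n_cases": config.n_cases,
            "n_controls": config.n_controls,
            "penetrances": list(config.penetrances),
            "top_fraction": config.top_fraction,
            "bin_width": config.bin_width,
            "poly_degree": config.poly_degree,
            "n_tail_bins_excluded": config.n_tail_bins_excluded,
            "seed": config.seed,
            "n_used": int(r2.size),
        },
        bin_table={
            "bin_mid": list(map(float, mids)),
            "n": list(map(int, counts[populated])),
            "p_top": list(map(float, probs)),
        },
    )
    grid = np.arange(0.0, 1.0005, 1e-3)
    peak = float(np.max(curve._raw(grid)))
    if peak <= 0.0:
        raise ValueError("degenerate metric curve: non-positive everywhere")
    curve.scale = 100.0 / peak
    return curve


def score(curve: MetricCurve, r2) -> float:
    """Evaluate ``curve`` at one r² value; UNDEFINED r² scores 0."""
    if r2 is UNDEFINED:
        return 0.0
    return float(curve.evaluate(float(r2)))


def default_curve(model_label: str = "multiplicative") -> MetricCurve:
    """Load one of the package's precomputed score curves."""
    if model_label not in MODEL_PENETRANCES:
        raise ValueError(f"unknown metric model {model_label!r}")
    ref = resources.files("snipscan").joinpath(f"data/metric_{model_label}.json")
    return MetricCurve.from_dict(json.loads(ref.read_text()))
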