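"""Two-sample MR causal estimators.

Implements the standard estimator battery: the Wald ratio for a single
instrument; inverse-variance-weighted (IVW) meta-analysis with fixed or
multiplicative random effects; MR-Egger regression (with its pleiotropy
intercept); the weighted median; and kernel-density mode estimators (simple
and weighted). Effects are on the log-odds (or SD) scale; odds ratios with
95% CIs are attached to every result via ``exp``.

Conventions
-----------
* Instrument weights are first-order: ``w_i = 1/se_y_i^2`` (exposure-side
  uncertainty enters only through MR-PRESSO's simulations and the
  bootstrap SEs of the median/mode estimators).
* The multiplicative random-effects (MRE) scale is truncated at 1, so the
  MRE SE is never smaller than the fixed-effect SE.
* p-values are two-sided normal for Wald/IVW/median/mode and t(k-2) for
  Egger.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .instruments import InstrumentSet

Z_95 = 1.959964  # two-sided 95% normal quantile


@dataclass
class MRResult:
    """A causal estimate from one method on one instrument set."""

    method: str
    n_snp: int
    beta: float
    se: float
    pval: float
    or_point: float
    or_low: float
    or_high: float
    extra: dict = field(default_factory=dict)


def to_odds_ratio(beta: float, se: float) -> tuple[float, float, float]:
    """Exponentiate a log-scale effect and its 95% CI bounds."""
    if se <= 0:
        raise ValueError("se must be positive")
    return math.exp(beta), math.exp(beta - Z_95 * se), math.exp(beta + Z_95 * se)


def _normal_p(beta: float, se: float) -> float:
    return float(2.0 * stats.norm.sf(abs(beta) / se))


def _result(method: str, n_snp: int, beta: float, se: float,
            pval: float | None = None, extra: dict | None = None) -> MRResult:
    or_point, or_low, or_high = to_odds_ratio(beta, se)
    if pval is None:
        pval = _normal_p(beta, se)
    return MRResult(method=method, n_snp=n_snp, beta=float(beta), se=float(se),
                    pval=float(pval), or_point=or_point, or_low=or_low,
                    or_high=or_high, extra=extra or {})


def mr_result_from_or(method: str, or_point: float, or_low: float, or_high: float,
                      pval: float | None = None, n_snp: int = 1) -> MRResult:
    """Build an MRResult from a published OR with its 95% CI.

    The log-scale SE is recovered as ``(ln hi - ln lo) / (2 * 1.959964)`` —
    useful for feeding printed results tables into downstream mediation.
    """
    beta = math.log(or_point)
    se = (math.log(or_high) - math.log(or_low)) / (2.0 * Z_95)
    if pval is None:
        pval = _normal_p(beta, se)
    return MRResult(method=method, n_snp=n_snp, beta=beta, se=se, pval=float(pval),
                    or_point=or_point, or_low=or_low, or_high=or_high)


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

def wald_ratio(s: InstrumentSet) -> MRResult:
    """Single-instrument causal estimate beta_y / beta_x.

    SE is the first-order delta approximation ``se_y / |beta_x|`` (the
    exposure-side uncertainty is ignored, standard two-sample MR practice).
    """
    if s.n_snp != 1:
        raise ValueError("wald_ratio requires exactly one instrument")
    bx, by, sey = s.beta_x[0], s.beta_y[0], s.se_y[0]
    if bx == 0:
        raise ValueError("wald_ratio undefined for beta_x = 0")
    return _result("wald_ratio", 1, by / bx, sey / abs(bx))


def _ivw_fit(beta_x, beta_y, se_y):
    w = 1.0 / se_y**2
    s_xx = float(np.sum(w * beta_x**2))
    beta = float(np.sum(w * beta_x * beta_y)) / s_xx
    se_fixed = s_xx**-0.5
    q = float(np.sum(w * (beta_y - beta * beta_x) ** 2))
    return beta, se_fixed, q


def ivw(s: InstrumentSet, model: str = "auto") -> MRResult:
    """Inverse-variance-weighted estimate (weighted regression through the origin).

    ``model``:
      * ``"fixed"`` — fixed-effect SE;
      * ``"mre"`` — multiplicative random effects, SE scaled by
        ``max(1, sqrt(Q/(k-1)))``;
      * ``"auto"`` — MRE iff the Cochran-Q heterogeneity p < .05, else fixed
        (switch rule used when heterogeneity is detected).
    """
    if model not in ("auto", "fixed", "mre"):
        raise ValueError(f"unknown IVW model {model!r}")
    k = s.n_snp
    if k < 2:
        raise ValueError("ivw requires >= 2 instruments; use wald_ratio for one")
    beta, se_fixed, q = _ivw_fit(s.beta_x, s.beta_y, s.se_y)
    q_pval = float(stats.chi2.sf(q, k - 1))
    if model == "auto":
        model = "mre" if q_pval < 0.05 else "fixed"
    if model == "mre":
        scale = max(1.0, math.sqrt(q / (k - 1)))
        se = se_fixed * scale
        method = "ivw_mre"
    else:
        se = se_fixed
        method = "ivw_fe"
    return _result(method, k, beta, se,
                   extra={"Q": q, "Q_df": k - 1, "Q_pval": q_pval})


def egger(s: InstrumentSet) -> MRResult:
    """MR-Egger: weighted regression of beta_y on beta_x with an intercept.

    Instruments are oriented so all beta_x >= 0 before fitting (the ratio
    sign convention); the intercept estimates average directional
    pleiotropy and is stored with its SE and p in ``extra``. SEs use the
    multiplicative scaling ``max(1, residual scale)``; p-values from
    t(k-2).
    """
    k = s.n_snp
    if k < 3:
        raise ValueError("egger requires >= 3 instruments")
    sign = np.where(s.beta_x < 0, -1.0, 1.0)
    bx = s.beta_x * sign
    by = s.beta_y * sign
    w = 1.0 / s.se_y**2
    X = np.column_stack([np.ones(k), bx])
    xtwx = X.T @ (w[:, None] * X)
    xtwy = X.T @ (w * by)
    coef = np.linalg.solve(xtwx, xtwy)
    resid = by - X @ coef
    sigma2 = float(np.sum(w * resid**2)) / (k - 2)
    cov = np.linalg.inv(xtwx) * max(1.0, sigma2)
    se_int, se_slope = np.sqrt(np.diag(cov))
    slope_p = float(2.0 * stats.t.sf(abs(coef[1]) / se_slope, k - 2))
    int_p = float(2.0 * stats.t.sf(abs(coef[0]) / se_int, k - 2))
    return _result("egger", k, coef[1], se_slope, pval=slope_p,
                   extra={"egger_intercept": float(coef[0]),
                          "egger_intercept_se": float(se_int),
                          "egger_intercept_pval": int_p,
                          "residual_scale": math.sqrt(max(1.0, sigma2))})


def _weighted_median(theta: np.ndarray, w: np.ndarray) -> float:
    order = np.argsort(theta)
    theta = theta[order]
    w = w[order] / np.sum(w)
    p = np.cumsum(w) - 0.5 * w
    if 0.5 <= p[0]:
        return float(theta[0])
    if 0.5 >= p[-1]:
        return float(theta[-1])
    return float(np.interp(0.5, p, theta))


def weighted_median(s: InstrumentSet, n_boot: int = 1000, seed: int = 0) -> MRResult:
    """Weight-interpolated 50th percentile of the per-SNP Wald ratios.

    Weights are ``beta_x^2 / se_y^2`` (inverse variance of each ratio to
    first order). The SE comes from a seeded parametric bootstrap that
    resamples beta_x and beta_y from normals with their reported SEs.
    """
    k = s.n_snp
    if k < 3:
        raise ValueError("weighted_median requires >= 3 instruments")
    theta = s.beta_y / s.beta_x
    w = s.beta_x**2 / s.se_y**2
    est = _weighted_median(theta, w)
    rng = np.random.default_rng(seed)
    bx = rng.normal(s.beta_x, s.se_x, size=(n_boot, k))
    by = rng.normal(s.beta_y, s.se_y, size=(n_boot, k))
    boots = np.empty(n_boot)
    for b in range(n_boot):
        boots[b] = _weighted_median(by[b] / bx[b], bx[b] ** 2 / s.se_y**2)
    se = float(np.std(boots))
    return _result("weighted_median", k, est, se)


def _kde_mode(theta: np.ndarray, w: np.ndarray, phi: float) -> float:
    sd = float(np.std(theta, ddof=1)) if len(theta) > 1 else 0.0
    mad = 1.4826 * float(np.median(np.abs(theta - np.median(theta))))
    h = phi * 0.9 * min(sd, mad if mad > 0 else sd) * len(theta) ** (-1 / 5)
    if h <= 0:  # all ratios (essentially) identical
        return float(theta[0])
    grid = np.linspace(theta.min() - 3 * h, theta.max() + 3 * h, 2048)
    dens = np.sum(w[None, :] * np.exp(-0.5 * ((grid[:, None] - theta[None, :]) / h) ** 2), axis=1)
    return float(grid[np.argmax(dens)])


def mode_estimate(s: InstrumentSet, weighted: bool = False, phi: float = 1.0,
                  n_boot: int = 1000, seed: int = 0) -> MRResult:
    """Kernel-density mode of the per-SNP Wald ratios (simple or weighted).

    Gaussian kernel with bandwidth ``phi * 0.9 * min(sd, 1.4826*MAD) *
    k^(-1/5)``; the weighted variant reuses the weighted-median weights.
    SE by seeded parametric bootstrap of the mode.
    """
    k = s.n_snp
    if k < 3:
        raise ValueError("mode_estimate requires >= 3 instruments")
    if phi <= 0:
        raise ValueError("phi must be positive")
    theta = s.beta_y / s.beta_x
    w = (s.beta_x**2 / s.se_y**2) if weighted else np.ones(k)
    w = w / np.sum(w)
    est = _kde_mode(theta, w, phi)
    rng = np.random.default_rng(seed)
    bx = rng.normal(s.beta_x, s.se_x, size=(n_boot, k))
    by = rng.normal(s.beta_y, s.se_y, size=(n_boot, k))
    boots = np.empty(n_boot)
    for b in range(n_boot):
        tb = by[b] / bx[b]
        wb = (bx[b] ** 2 / s.se_y**2) if weighted else np.ones(k)
        boots[b] = _kde_mode(tb, wb / np.sum(wb), phi)
    se = float(np.std(boots))
    method = "weighted_mode" if weighted else "simple_mode"
    return _result(method, k, est, se)


def primary_estimate(s: InstrumentSet, seed: int = 0) -> MRResult:
    """The scan's primary estimator: Wald ratio for one SNP, IVW otherwise."""
    return wald_ratio(s) if s.n_snp == 1 else ivw(s, model="auto")


ALL_METHODS = ("ivw", "egger", "weighted_median", "simple_mode", "weighted_mode")


def run_methods(s: InstrumentSet, methods=ALL_METHODS, seed: int = 0) -> list[MRResult]:
    """Run a battery of estimators, skipping those whose minimum instrument
    count the set does not meet (a single-SNP set falls back to the Wald ratio)."""
    if s.n_snp == 1:
        return [wald_ratio(s)]
    out = []
    for m in methods:
        if m == "ivw":
            out.append(ivw(s))
        elif m == "egger" and s.n_snp >= 3:
            out.append(egger(s))
        elif m == "weighted_median" and s.n_snp >= 3:
            out.append(weighted_median(s, seed=seed))
        elif m == "simple_mode" and s.n_snp >= 3:
            out.append(mode_estimate(s, weighted=False, seed=seed))
        elif m == "weighted_mode" and s.n_snp >= 3:
            out.append(mode_estimate(s, weighted=True, seed=seed))
    return out
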