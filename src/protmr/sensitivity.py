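"""Heterogeneity, pleiotropy, outlier, and directionality diagnostics.

* :func:`cochran_q` — weighted heterogeneity statistic around the fixed-
  effect IVW slope, chi-square(k-1) tail p.
* :func:`egger_intercept_test` — the MR-Egger intercept as a directional-
  pleiotropy test (p > .05 read as no evidence of pleiotropy).
* :func:`mr_presso` — simulation-based global pleiotropy test and per-SNP
  outlier detection from leave-one-out residuals, with an outlier-corrected
  estimate and a distortion test.
* :func:`steiger_filter` — per-SNP causal-direction check comparing variance
  explained in exposure vs outcome (r^2 recovered from p and n), keeping
  only "TRUE"-direction instruments.
* :func:`bidirectional_mr` — the forward analysis paired with the reverse
  orientation (outcome as exposure) to flag reverse causation.

Empirical p-values use the (1 + count)/(n + 1) estimator so they are never
zero.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .gwas_io import TraitMeta
from .instruments import InstrumentSet
from .mr import MRResult, _ivw_fit, ivw, primary_estimate

log = logging.getLogger("protmr")


@dataclass
class HeterogeneityResult:
    Q: float
    df: int
    pval: float


@dataclass
class PressoResult:
    rss_observed: float
    global_pval: float
    outlier_indices: list[int]
    outlier_pvals: np.ndarray  # Bonferroni-adjusted, capped at 1
    distortion_pval: float | None
    corrected: MRResult | None
    n_sim: int
    seed: int


@dataclass
class SteigerResult:
    snp_ids: np.ndarray
    r2_exposure: np.ndarray
    r2_outcome: np.ndarray
    direction_true: np.ndarray  # per-SNP boolean
    overall_direction_true: bool
    steiger_pval: float


@dataclass
class BidirectionalResult:
    forward: MRResult
    reverse: MRResult | None
    reverse_causation_flag: bool
    note: str = ""


def cochran_q(s: InstrumentSet) -> HeterogeneityResult:
    """Cochran's Q around the fixed-effect IVW slope.

    Q = sum_i (beta_y_i - theta_IVW * beta_x_i)^2 / se_y_i^2, compared to
    chi-square with k-1 degrees of freedom.
    """
    if s.n_snp < 2:
        raise ValueError("cochran_q requires >= 2 instruments")
    _, _, q = _ivw_fit(s.beta_x, s.beta_y, s.se_y)
    df = s.n_snp - 1
    return HeterogeneityResult(Q=q, df=df, pval=float(stats.chi2.sf(q, df)))


def egger_intercept_test(s: InstrumentSet) -> tuple[float, float, float]:
    """(intercept, SE, p) of the MR-Egger intercept — same numbers as
    :func:`protmr.mr.egger` reports in ``extra``."""
    from .mr import egger

    res = egger(s)
    return (res.extra["egger_intercept"], res.extra["egger_intercept_se"],
            res.extra["egger_intercept_pval"])


# ---------------------------------------------------------------------------
# MR-PRESSO
# ---------------------------------------------------------------------------

def _loo_slopes(beta_x: np.ndarray, beta_y: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out fixed-effect IVW slopes, vectorized over the left-out SNP.

    Supports batched inputs of shape (..., k); weights broadcast.
    """
    s_xy = np.sum(w * beta_x * beta_y, axis=-1, keepdims=True)
    s_xx = np.sum(w * beta_x**2, axis=-1, keepdims=True)
    return (s_xy - w * beta_x * beta_y) / (s_xx - w * beta_x**2)


def mr_presso(s: InstrumentSet, n_sim: int = 1000, outlier_alpha: float = 0.05,
              seed: int = 0) -> PressoResult:
    """MR-PRESSO global pleiotropy test and outlier correction.

    The observed residual sum of squares uses leave-one-out IVW slopes:
    RSS = sum_i (beta_y_i - theta_{-i} beta_x_i)^2. Its null distribution is
    built by parametric simulation (beta_x* ~ N(beta_x, se_x), beta_y* ~
    N(theta_{-i} beta_x, se_y)), recomputing the leave-one-out residuals each
    time. Per-SNP outlier p-values come from each SNP's simulated squared-
    residual distribution, Bonferroni-multiplied by k; when outliers are
    flagged, an IVW estimate on the remaining SNPs and a bootstrap
    distortion p-value are attached.
    """
    k = s.n_snp
    if k < 4:
        raise ValueError("mr_presso requires >= 4 instruments")
    if n_sim < 100:
        raise ValueError("n_sim must be >= 100")
    w = 1.0 / s.se_y**2
    theta_loo = _loo_slopes(s.beta_x, s.beta_y, w)
    resid2_obs = (s.beta_y - theta_loo * s.beta_x) ** 2
    rss_obs = float(np.sum(resid2_obs))

    rng = np.random.default_rng([seed, 0])
    bx = rng.normal(s.beta_x, s.se_x, size=(n_sim, k))
    by = rng.normal(theta_loo * s.beta_x, s.se_y, size=(n_sim, k))
    theta_loo_sim = _loo_slopes(bx, by, w)
    resid2_sim = (by - theta_loo_sim * bx) ** 2
    rss_sim = np.sum(resid2_sim, axis=1)

    global_pval = (1.0 + np.sum(rss_sim >= rss_obs)) / (n_sim + 1.0)
    per_snp_p = (1.0 + np.sum(resid2_sim >= resid2_obs[None, :], axis=0)) / (n_sim + 1.0)
    outlier_p = np.minimum(per_snp_p * k, 1.0)
    outliers = [int(i) for i in np.flatnonzero(outlier_p < outlier_alpha)]

    corrected = None
    distortion_pval = None
    keep = np.setdiff1d(np.arange(k), outliers)
    if outliers and len(keep) >= 2:
        corrected = ivw(s.subset(keep), model="fixed")
        # distortion null: IVW slopes on bootstrap resamples of the
        # outlier-free SNPs, compared against the original-vs-corrected gap
        theta_all, _, _ = _ivw_fit(s.beta_x, s.beta_y, s.se_y)
        d_obs = theta_all - corrected.beta
        rng_d = np.random.default_rng([seed, 1])
        n_boot = 1000
        idx = rng_d.choice(keep, size=(n_boot, len(keep)), replace=True)
        bxb, byb, seb = s.beta_x[idx], s.beta_y[idx], s.se_y[idx]
        wb = 1.0 / seb**2
        theta_b = np.sum(wb * bxb * byb, axis=1) / np.sum(wb * bxb**2, axis=1)
        d_null = theta_b - corrected.beta
        distortion_pval = float((1.0 + np.sum(np.abs(d_null) >= abs(d_obs))) / (n_boot + 1.0))

    return PressoResult(rss_observed=rss_obs, global_pval=float(global_pval),
                        outlier_indices=outliers, outlier_pvals=outlier_p,
                        distortion_pval=distortion_pval, corrected=corrected,
                        n_sim=n_sim, seed=seed)


# ---------------------------------------------------------------------------
# Steiger directionality
# ---------------------------------------------------------------------------

def _r2_from_p(pval: np.ndarray, n: int) -> np.ndarray:
    """Variance explained implied by a p-value at sample size n:
    r^2 = F/(F + n - 2) with F the (1-p) quantile of F(1, n-2).

    For extreme p the F inverse-survival function overflows; the equivalent
    t- and normal-quantile squares are used as successive fallbacks.
    """
    pval = np.atleast_1d(np.asarray(pval, dtype=float))
    f = stats.f.isf(pval, 1, n - 2)
    bad = ~np.isfinite(f)
    if np.any(bad):
        f[bad] = stats.t.isf(pval[bad] / 2.0, n - 2) ** 2
    bad = ~np.isfinite(f)
    if np.any(bad):
        f[bad] = stats.norm.isf(pval[bad] / 2.0) ** 2
    return f / (f + n - 2)


def steiger_filter(
    s: InstrumentSet,
    exposure: TraitMeta | None = None,
    outcome: TraitMeta | None = None,
) -> tuple[SteigerResult, InstrumentSet]:
    """Causal-direction filter: keep SNPs explaining more variance in the
    exposure than in the outcome.

    Per-SNP r^2 values are recovered from each trait's p-value and sample
    size. A SNP's direction is TRUE iff r2_exposure > r2_outcome; the
    overall direction compares summed r^2 and its p-value comes from a
    two-sample Fisher-z test of the implied correlations. Binary traits use
    the same observed-scale approximation as quantitative traits.
    """
    exposure = exposure or s.exposure
    outcome = outcome or s.outcome
    n_exp, n_out = exposure.sample_size, outcome.sample_size
    if n_exp <= 3 or n_out <= 3:
        raise ValueError("steiger_filter requires sample sizes > 3")
    r2_exp = _r2_from_p(s.pval_x, n_exp)
    r2_out = _r2_from_p(s.pval_y, n_out)
    direction = r2_exp > r2_out
    tot_exp = min(float(np.sum(r2_exp)), 1.0 - 1e-12)
    tot_out = min(float(np.sum(r2_out)), 1.0 - 1e-12)
    z_exp = np.arctanh(math.sqrt(tot_exp))
    z_out = np.arctanh(math.sqrt(tot_out))
    z = (z_exp - z_out) / math.sqrt(1.0 / (n_exp - 3) + 1.0 / (n_out - 3))
    pval = float(2.0 * stats.norm.sf(abs(z)))
    result = SteigerResult(snp_ids=s.snp_ids.copy(), r2_exposure=r2_exp,
                           r2_outcome=r2_out, direction_true=direction,
                           overall_direction_true=tot_exp > tot_out,
                           steiger_pval=pval)
    if not np.any(direction):
        log.info("steiger_filter removed every instrument")
    return result, s.subset(direction)


def bidirectional_mr(forward: InstrumentSet,
                     reverse: InstrumentSet | None) -> BidirectionalResult:
    """Forward MR paired with the reverse orientation.

    ``reverse`` is the instrument set built by the same selection pipeline
    with outcome and exposure swapped, or None when no reverse instruments
    survive selection (reported as "not estimable", not an error). The
    reverse-causation flag is raised when the reverse p < .05.
    """
    fwd = primary_estimate(forward)
    if reverse is None or reverse.n_snp == 0:
        return BidirectionalResult(forward=fwd, reverse=None,
                                   reverse_causation_flag=False,
                                   note="reverse not estimable (no instruments)")
    rev = primary_estimate(reverse)
    return BidirectionalResult(forward=fwd, reverse=rev,
                               reverse_causation_flag=rev.pval < 0.05)
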