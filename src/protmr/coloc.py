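"""Bayesian colocalization of two traits in a genomic region.

Under a single-causal-variant assumption per trait, each SNP's evidence of
association is summarized by a Wakefield log approximate Bayes factor
(lABF), and the region-level evidence for five mutually exclusive
hypotheses is accumulated:

* H0 — neither trait has a causal variant in the region;
* H1 / H2 — only trait 1 / only trait 2 does;
* H3 — both do, but at different variants;
* H4 — both do, at the same shared variant.

Posterior probabilities PPH0..PPH4 are returned; PPH4 >= 0.8 (inclusive) is
the conventional threshold for strong colocalization support. All evidence
sums are carried in log space so the computation is stable for |z| well
beyond 100.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .gwas_io import SummaryRecord

#: default per-SNP prior probabilities of association
PRIOR_P1 = 1e-4
PRIOR_P2 = 1e-4
PRIOR_P12 = 1e-5
#: default prior SD of true effects, by trait type
PRIOR_SD = {"quantitative": 0.15, "binary": 0.2}

H3_TOL = 1e-9  # relative tolerance for the H3 log-difference


@dataclass
class ColocResult:
    n_snps: int
    pph0: float
    pph1: float
    pph2: float
    pph3: float
    pph4: float
    priors: tuple[float, float, float]
    log_sums: dict

    @property
    def posteriors(self) -> np.ndarray:
        return np.array([self.pph0, self.pph1, self.pph2, self.pph3, self.pph4])


def labf(beta: float, se: float, prior_sd: float) -> float:
    """Wakefield log approximate Bayes factor for one SNP.

    With z = beta/se and shrinkage r = prior_sd^2/(prior_sd^2 + se^2):
    lABF = 0.5*(log(1 - r) + r*z^2).
    """
    if se <= 0:
        raise ValueError("se must be positive")
    if prior_sd <= 0:
        raise ValueError("prior_sd must be positive")
    z = beta / se
    r = prior_sd**2 / (prior_sd**2 + se**2)
    return 0.5 * (math.log1p(-r) + r * z * z)


def _labf_vec(beta: np.ndarray, se: np.ndarray, prior_sd: float) -> np.ndarray:
    z = beta / se
    r = prior_sd**2 / (prior_sd**2 + se**2)
    return 0.5 * (np.log1p(-r) + r * z * z)


def coloc_abf(
    region1: Sequence[SummaryRecord],
    region2: Sequence[SummaryRecord],
    p1: float = PRIOR_P1,
    p2: float = PRIOR_P2,
    p12: float = PRIOR_P12,
    trait_types: tuple[str, str] = ("quantitative", "quantitative"),
) -> ColocResult:
    """Posterior probabilities of the five colocalization hypotheses.

    The two regions are intersected on snp_id (effect alignment is not
    needed: the evidence depends on beta/se only through z^2). Per-
    hypothesis evidence uses S1 = sum_i exp(lABF1_i), S2 analogously, and
    S12 = sum_i exp(lABF1_i + lABF2_i):

        H0 ∝ 1,  H1 ∝ p1*S1,  H2 ∝ p2*S2,
        H3 ∝ p1*p2*(S1*S2 - S12),  H4 ∝ p12*S12,

    all accumulated with log-sum-exp.
    """
    by_id2 = {r.snp_id: r for r in region2}
    pairs = [(r, by_id2[r.snp_id]) for r in region1 if r.snp_id in by_id2]
    if not pairs:
        raise ValueError("coloc_abf: no SNPs shared between the two regions")
    sd1 = PRIOR_SD[trait_types[0]]
    sd2 = PRIOR_SD[trait_types[1]]
    l1 = _labf_vec(np.array([a.beta for a, _ in pairs]),
                   np.array([a.se for a, _ in pairs]), sd1)
    l2 = _labf_vec(np.array([b.beta for _, b in pairs]),
                   np.array([b.se for _, b in pairs]), sd2)

    log_s1 = float(logsumexp(l1))
    log_s2 = float(logsumexp(l2))
    log_s12 = float(logsumexp(l1 + l2))

    log_h0 = 0.0
    log_h1 = math.log(p1) + log_s1
    log_h2 = math.log(p2) + log_s2
    log_h4 = math.log(p12) + log_s12
    # H3's cross-variant sum is S1*S2 minus the shared-variant diagonal
    gap = log_s12 - (log_s1 + log_s2)
    if gap > H3_TOL:
        raise ArithmeticError(f"coloc_abf: negative H3 evidence (log gap {gap:.3e})")
    if len(pairs) == 1 or gap >= 0.0:
        log_h3 = -math.inf  # no cross-variant configurations
    else:
        log_h3 = math.log(p1) + math.log(p2) + log_s1 + log_s2 + math.log1p(-math.exp(gap))
        if not math.isfinite(log_h3):
            log_h3 = -math.inf

    logs = np.array([log_h0, log_h1, log_h2, log_h3, log_h4])
    log_z = logsumexp(logs)
    post = np.exp(logs - log_z)
    return ColocResult(
        n_snps=len(pairs),
        pph0=float(post[0]), pph1=float(post[1]), pph2=float(post[2]),
        pph3=float(post[3]), pph4=float(post[4]),
        priors=(p1, p2, p12),
        log_sums={"log_s1": log_s1, "log_s2": log_s2, "log_s12": log_s12,
                  "log_h": logs.tolist()},
    )


def coloc_report(results: dict[str, ColocResult], threshold: float = 0.8) -> pd.DataFrame:
    """Tabulate per-protein colocalization posteriors with a flag column.

    A protein is flagged colocalized iff PPH4 >= threshold (inclusive).
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie in (0, 1)")
    rows = []
    for name, res in results.items():
        rows.append({
            "id": name, "n_snps": res.n_snps,
            "pph0": res.pph0, "pph1": res.pph1, "pph2": res.pph2,
            "pph3": res.pph3, "pph4": res.pph4,
            "colocalized": bool(res.pph4 >= threshold),
        })
    return pd.DataFrame(rows)
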