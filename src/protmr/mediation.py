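"""Two-step MR mediation: decomposing a total causal effect.

The total effect of an exposure on the outcome is split into a direct
component and an indirect component carried by a mediator, using the
product-of-coefficients method on log-scale effects:

    indirect = beta_1 * beta_2          (exposure->mediator, mediator->outcome)
    direct   = total - indirect         (difference form, exact by construction)
    proportion mediated = 100 * indirect / total   (percent)

Standard errors for the indirect effect and the proportion use the delta
method. Inconsistent mediation (indirect and total of opposite sign) yields
a negative proportion with a warning rather than an error.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from .mr import MRResult

log = logging.getLogger("protmr")


@dataclass
class MediationResult:
    exposure: str
    mediator: str
    total: MRResult
    step1: MRResult  # exposure -> mediator
    step2: MRResult  # mediator -> outcome
    indirect_beta: float
    indirect_se: float
    direct_beta: float
    proportion: float  # percent of the total effect mediated
    proportion_se: float
    warning: str = ""


def two_step_mediation(total: MRResult, step1: MRResult, step2: MRResult,
                       exposure: str = "exposure",
                       mediator: str = "mediator") -> MediationResult:
    """Product-method mediation decomposition from three MR estimates.

    All three results must be on the log scale (betas, not ORs); use
    :func:`protmr.mr.mr_result_from_or` to convert published OR tables.
    """
    if total.beta == 0.0:
        raise ValueError("total effect is zero: mediated proportion undefined")
    b1, b2, bt = step1.beta, step2.beta, total.beta
    indirect = b1 * b2
    indirect_se = math.sqrt(b2**2 * step1.se**2 + b1**2 * step2.se**2)
    direct = bt - indirect
    proportion = 100.0 * indirect / bt
    proportion_se = 100.0 * math.sqrt(
        indirect_se**2 / bt**2 + indirect**2 * total.se**2 / bt**4
    )
    warning = ""
    if indirect != 0.0 and math.copysign(1, indirect) != math.copysign(1, bt):
        warning = "inconsistent mediation: indirect and total effects have opposite signs"
        log.warning("%s via %s: %s", exposure, mediator, warning)
    return MediationResult(exposure=exposure, mediator=mediator, total=total,
                           step1=step1, step2=step2,
                           indirect_beta=indirect, indirect_se=indirect_se,
                           direct_beta=direct, proportion=proportion,
                           proportion_se=proportion_se, warning=warning)


def mediation_screen(
    totals: dict[str, MRResult],
    step1_results: dict[tuple[str, str], MRResult],
    step2_results: dict[str, MRResult],
    alpha: float = 0.05,
) -> tuple[list[MediationResult], list[tuple[tuple[str, str], str]]]:
    """Run mediation for every exposure-mediator chain passing both filters.

    A chain (exposure, mediator) is analyzed only when the exposure->mediator
    estimate has p < ``alpha`` AND the mediator->outcome estimate has
    p < ``alpha``. Skipped chains are returned with their reason.
    """
    results: list[MediationResult] = []
    skipped: list[tuple[tuple[str, str], str]] = []
    for (exposure, mediator), s1 in sorted(step1_results.items()):
        chain = (exposure, mediator)
        if exposure not in totals:
            skipped.append((chain, "no total-effect estimate for exposure"))
            continue
        s2 = step2_results.get(mediator)
        if s2 is None:
            skipped.append((chain, "no mediator->outcome estimate"))
            continue
        if not (s1.pval < alpha):
            skipped.append((chain, "step1 not significant"))
            continue
        if not (s2.pval < alpha):
            skipped.append((chain, "step2 not significant"))
            continue
        results.append(two_step_mediation(totals[exposure], s1, s2,
                                          exposure=exposure, mediator=mediator))
    for chain, reason in skipped:
        log.info("mediation chain %s skipped: %s", chain, reason)
    return results, skipped
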