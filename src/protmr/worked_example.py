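"""Worked mediation examples from a published duodenal-ulcer protein scan.

A proteome-wide MR study of plasma proteins and duodenal ulcer reported,
among its results, odds ratios (with 95% CIs) for three protein ->
risk-factor -> disease chains, together with the mediated proportions
obtained by the product method. Those printed ORs are reproduced here as a
small input table so the mediation decomposition can be recomputed from
published numbers alone — a worked example and an end-to-end check of
:func:`protmr.mediation.two_step_mediation` on real reported values.

Because the published ORs are rounded to four decimals, the recomputed
proportions match the printed percentages to about +-0.1 percentage points.
"""

from __future__ import annotations

from .mediation import MediationResult, two_step_mediation
from .mr import mr_result_from_or

#: published OR (point, low, high) triples: total protein->disease effects,
#: protein->mediator effects, and mediator->disease effects
PUBLISHED_ORS = {
    ("IL6ST", "disease"): (1.0026, 1.0015, 1.0037),
    ("GOLM1", "disease"): (0.9978, 0.9969, 0.9988),
    ("REG1B", "disease"): (0.9979, 0.9971, 0.9986),
    ("IL6ST", "alcohol_per_week"): (1.0126, 1.0024, 1.0230),
    ("GOLM1", "alcohol_per_week"): (0.9822, 0.9684, 0.9962),
    ("REG1B", "poor_diet"): (0.9832, 0.9708, 0.9957),
    ("alcohol_per_week", "disease"): (1.0044, 1.0017, 1.0070),
    ("poor_diet", "disease"): (1.0009, 1.0005, 1.0012),
}

#: the three recomputable chains with their published mediated proportions (%)
CHAINS = [
    ("IL6ST", "alcohol_per_week", 2.10),
    ("GOLM1", "alcohol_per_week", 3.50),
    ("REG1B", "poor_diet", 0.70),
]


def mediation_worked_examples() -> list[tuple[MediationResult, float]]:
    """Recompute the three published mediated proportions from printed ORs.

    Returns (result, published_percent) pairs, one per chain.
    """
    out = []
    for exposure, mediator, published in CHAINS:
        total = mr_result_from_or("ivw", *PUBLISHED_ORS[(exposure, "disease")])
        step1 = mr_result_from_or("ivw", *PUBLISHED_ORS[(exposure, mediator)])
        step2 = mr_result_from_or("ivw", *PUBLISHED_ORS[(mediator, "disease")])
        res = two_step_mediation(total, step1, step2,
                                 exposure=exposure, mediator=mediator)
        out.append((res, published))
    return out
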