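"""Benjamini-Hochberg false-discovery-rate control across a scan.

The FDR family is all tests submitted in one call — in the proteome-wide
scan, all proteins tested against one outcome. Significance is strict:
q < alpha.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests


def bh_fdr(pvals: Sequence[float], alpha: float = 0.05,
           ids: Sequence[str] | None = None) -> pd.DataFrame:
    """BH step-up adjusted q-values with a strict q < alpha significance flag.

    Returns a DataFrame with columns ``id``, ``pval``, ``qval``,
    ``significant``, in the input order.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("bh_fdr requires at least one p-value")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    if ids is None:
        ids = [str(i) for i in range(p.size)]
    return pd.DataFrame({
        "id": list(ids),
        "pval": p,
        "qval": q,
        "significant": q < alpha,
    })
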