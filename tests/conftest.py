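import numpy as np
import pytest

from protmr.gwas_io import SummaryRecord, TraitMeta
from protmr.instruments import InstrumentSet

NON_PALINDROMIC = [("A", "C"), ("A", "G"), ("C", "T"), ("G", "T")]


def make_record(snp_id="rs1", chrom="1", pos=1000, ea="A", oa="G", eaf=0.3,
                beta=0.1, se=0.01, pval=1e-10, n=10000, **kw) -> SummaryRecord:
    return SummaryRecord(snp_id=snp_id, chrom=chrom, pos=pos, effect_allele=ea,
                         other_allele=oa, eaf=eaf, beta=beta, se=se, pval=pval,
                         n=n, **kw)


def make_set(beta_x, beta_y, se_y, se_x=None, pval_x=None, pval_y=None,
             n_exp=30000, n_out=400000) -> InstrumentSet:
    """Build an InstrumentSet directly from effect arrays."""
    beta_x = np.asarray(beta_x, dtype=float)
    beta_y = np.asarray(beta_y, dtype=float)
    k = len(beta_x)
    se_y = np.broadcast_to(np.asarray(se_y, dtype=float), (k,)).copy()
    se_x = (np.full(k, 0.005) if se_x is None
            else np.broadcast_to(np.asarray(se_x, dtype=float), (k,)).copy())
    from scipy import stats
    if pval_x is None:
        pval_x = np.maximum(2 * stats.norm.sf(np.abs(beta_x) / se_x), 1e-300)
    if pval_y is None:
        pval_y = np.maximum(2 * stats.norm.sf(np.abs(beta_y) / se_y), 1e-300)
    alleles = [NON_PALINDROMIC[i % 4] for i in range(k)]
    return InstrumentSet(
        snp_ids=np.array([f"rs{i + 1}" for i in range(k)], dtype=object),
        chrom=np.array(["1"] * k, dtype=object),
        pos=np.arange(1, k + 1) * 1_000_000,
        beta_x=beta_x, se_x=se_x, pval_x=np.asarray(pval_x, dtype=float),
        eaf_x=np.full(k, 0.3),
        beta_y=beta_y, se_y=se_y, pval_y=np.asarray(pval_y, dtype=float),
        eaf_y=np.full(k, 0.3),
        effect_allele=np.array([a for a, _ in alleles], dtype=object),
        other_allele=np.array([b for _, b in alleles], dtype=object),
        exposure=TraitMeta("exposure", "quantitative", n_exp),
        outcome=TraitMeta("outcome", "quantitative", n_out),
    )


def swap_xy(s: InstrumentSet) -> InstrumentSet:
    """Exchange the exposure and outcome sides of an instrument set."""
    return InstrumentSet(
        snp_ids=s.snp_ids, chrom=s.chrom, pos=s.pos,
        beta_x=s.beta_y, se_x=s.se_y, pval_x=s.pval_y, eaf_x=s.eaf_y,
        beta_y=s.beta_x, se_y=s.se_x, pval_y=s.pval_x, eaf_y=s.eaf_x,
        effect_allele=s.effect_allele, other_allele=s.other_allele,
        exposure=s.outcome, outcome=s.exposure,
    )


@pytest.fixture
def proportional_set() -> InstrumentSet:
    """Five instruments whose Wald ratios are all exactly 0.5."""
    bx = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
    return make_set(bx, 0.5 * bx, se_y=0.01)
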