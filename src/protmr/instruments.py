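"""Instrument selection and harmonization for two-sample MR.

Three steps turn raw exposure and outcome summary statistics into an
analysis-ready :class:`InstrumentSet`:

1. :func:`select_significant` — keep genome-wide-significant exposure SNPs
   (default threshold p < 5e-8, strict inequality);
2. :func:`clump` — greedy p-value-ordered LD pruning (PLINK convention,
   default r^2 > 0.001 within +-10,000 kb discards the weaker SNP);
3. :func:`harmonize` — align outcome effects to the exposure's effect
   allele, resolving strand flips and dropping ambiguous palindromic SNPs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .gwas_io import LDMatrix, SummaryRecord, TraitMeta

log = logging.getLogger("protmr")

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

GENOME_WIDE_P = 5e-8
CLUMP_R2 = 0.001
CLUMP_WINDOW_KB = 10_000.0
PALINDROME_EAF_WINDOW = (0.42, 0.58)


def is_palindromic(ea: str, oa: str) -> bool:
    """A/T or C/G pairs read the same on both strands."""
    return COMPLEMENT[ea] == oa


@dataclass
class InstrumentSet:
    """Harmonized per-SNP exposure/outcome effect pairs for one analysis.

    All outcome effects (``beta_y``) refer to the same allele as the
    exposure effects (``beta_x``).
    """

    snp_ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    beta_x: np.ndarray
    se_x: np.ndarray
    pval_x: np.ndarray
    eaf_x: np.ndarray
    beta_y: np.ndarray
    se_y: np.ndarray
    pval_y: np.ndarray
    eaf_y: np.ndarray
    effect_allele: np.ndarray
    other_allele: np.ndarray
    exposure: TraitMeta
    outcome: TraitMeta

    def __post_init__(self) -> None:
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        for name in ("beta_x", "se_x", "pval_x", "eaf_x", "beta_y", "se_y", "pval_y", "eaf_y"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValueError("duplicate snp_id in InstrumentSet")
        if np.any(self.se_x <= 0) or np.any(self.se_y <= 0):
            raise ValueError("all standard errors must be positive")

    @property
    def n_snp(self) -> int:
        return len(self.snp_ids)

    def __len__(self) -> int:
        return len(self.snp_ids)

    def subset(self, idx) -> "InstrumentSet":
        """A new InstrumentSet restricted to the given indices / boolean mask."""
        idx = np.asarray(idx)
        return InstrumentSet(
            snp_ids=self.snp_ids[idx],
            chrom=np.asarray(self.chrom, dtype=object)[idx],
            pos=np.asarray(self.pos)[idx],
            beta_x=self.beta_x[idx],
            se_x=self.se_x[idx],
            pval_x=self.pval_x[idx],
            eaf_x=self.eaf_x[idx],
            beta_y=self.beta_y[idx],
            se_y=self.se_y[idx],
            pval_y=self.pval_y[idx],
            eaf_y=self.eaf_y[idx],
            effect_allele=np.asarray(self.effect_allele, dtype=object)[idx],
            other_allele=np.asarray(self.other_allele, dtype=object)[idx],
            exposure=self.exposure,
            outcome=self.outcome,
        )

    def to_records(self) -> tuple[list[SummaryRecord], list[SummaryRecord]]:
        """Back-convert into aligned (exposure, outcome) record lists."""
        exp, out = [], []
        for i in range(self.n_snp):
            common = dict(
                snp_id=str(self.snp_ids[i]),
                chrom=str(self.chrom[i]),
                pos=int(self.pos[i]),
                effect_allele=str(self.effect_allele[i]),
                other_allele=str(self.other_allele[i]),
            )
            exp.append(SummaryRecord(eaf=self.eaf_x[i], beta=self.beta_x[i],
                                     se=self.se_x[i], pval=self.pval_x[i],
                                     n=self.exposure.sample_size, **common))
            out.append(SummaryRecord(eaf=self.eaf_y[i], beta=self.beta_y[i],
                                     se=self.se_y[i], pval=self.pval_y[i],
                                     n=self.outcome.sample_size, **common))
        return exp, out


def select_significant(
    records: Sequence[SummaryRecord], p_threshold: float = GENOME_WIDE_P
) -> list[SummaryRecord]:
    """Keep records with p strictly below the significance threshold.

    Original order is preserved; an empty result is allowed (logged).
    """
    if not (0.0 < p_threshold < 1.0):
        raise ValueError("p_threshold must lie in (0, 1)")
    kept = [r for r in records if r.pval < p_threshold]
    if not kept:
        log.info("no records pass p < %g", p_threshold)
    return kept


def clump(
    records: Sequence[SummaryRecord],
    ld: LDMatrix,
    r2_threshold: float = CLUMP_R2,
    window_kb: float = CLUMP_WINDOW_KB,
) -> list[SummaryRecord]:
    """Greedy p-value-ordered LD clumping.

    Repeatedly keep the remaining SNP with the smallest p (ties broken by
    (chrom, pos) for determinism) and discard every other SNP on the same
    chromosome within +-``window_kb`` whose squared correlation with it
    exceeds ``r2_threshold``. Kept records are returned sorted by
    (chrom, pos), so the output is independent of input row order.
    """
    for r in records:
        if r.snp_id not in ld:
            raise ValueError(f"SNP {r.snp_id} missing from LD matrix")
    window_bp = window_kb * 1000.0
    order = sorted(records, key=lambda r: (r.pval, r.chrom, r.pos))
    kept: list[SummaryRecord] = []
    removed: set[str] = set()
    for rec in order:
        if rec.snp_id in removed:
            continue
        kept.append(rec)
        for other in order:
            if other.snp_id == rec.snp_id or other.snp_id in removed:
                continue
            if other.chrom != rec.chrom or abs(other.pos - rec.pos) > window_bp:
                continue
            if ld.r2(rec.snp_id, other.snp_id) > r2_threshold:
                removed.add(other.snp_id)
    return sorted(kept, key=lambda r: (r.chrom, r.pos))


def _orientation(x: SummaryRecord, y: SummaryRecord) -> str | None:
    """How outcome alleles relate to exposure alleles for non-palindromic SNPs.

    Returns "same", "flip", or None for an unresolvable allele mismatch.
    Strand flips (both alleles complemented) are treated as "same"/"flip"
    accordingly.
    """
    ex, ox = x.effect_allele, x.other_allele
    ey, oy = y.effect_allele, y.other_allele
    if (ey, oy) == (ex, ox) or (ey, oy) == (COMPLEMENT[ex], COMPLEMENT[ox]):
        return "same"
    if (ey, oy) == (ox, ex) or (ey, oy) == (COMPLEMENT[ox], COMPLEMENT[ex]):
        return "flip"
    return None


def harmonize(
    exposure_records: Sequence[SummaryRecord],
    outcome_records: Sequence[SummaryRecord],
    palindrome_eaf_window: tuple[float, float] = PALINDROME_EAF_WINDOW,
    exposure: TraitMeta | None = None,
    outcome: TraitMeta | None = None,
) -> InstrumentSet:
    """Align outcome effects to the exposure's effect allele.

    SNPs are intersected on id. For non-palindromic SNPs a swapped outcome
    allele pair flips ``beta_y`` and ``eaf_y``; strand flips are resolved by
    complementing. Palindromic SNPs (A/T, C/G) carry no strand information in
    their allele labels, so they are oriented by EAF concordance — and
    dropped as ambiguous when either trait's EAF falls inside
    ``palindrome_eaf_window`` (default [0.42, 0.58]). Allele pairs that
    cannot be reconciled are dropped with a logged count.
    """
    lo, hi = palindrome_eaf_window
    out_by_id = {r.snp_id: r for r in outcome_records}
    rows = []
    n_palindromic_dropped = 0
    n_mismatch = 0
    for x in exposure_records:
        y = out_by_id.get(x.snp_id)
        if y is None:
            continue
        if is_palindromic(x.effect_allele, x.other_allele):
            if {y.effect_allele, y.other_allele} != {x.effect_allele, x.other_allele}:
                n_mismatch += 1
                continue
            if lo <= x.eaf <= hi or lo <= y.eaf <= hi:
                n_palindromic_dropped += 1
                continue
            # allele labels are strand-ambiguous; align by frequency concordance
            if (x.eaf < 0.5) == (y.eaf < 0.5):
                beta_y, eaf_y = y.beta, y.eaf
            else:
                beta_y, eaf_y = -y.beta, 1.0 - y.eaf
        else:
            orient = _orientation(x, y)
            if orient is None:
                n_mismatch += 1
                continue
            if orient == "same":
                beta_y, eaf_y = y.beta, y.eaf
            else:
                beta_y, eaf_y = -y.beta, 1.0 - y.eaf
        rows.append((x, y, beta_y, eaf_y))

    if n_palindromic_dropped:
        log.info("harmonize: dropped %d ambiguous palindromic SNP(s)", n_palindromic_dropped)
    if n_mismatch:
        log.info("harmonize: dropped %d SNP(s) with irreconcilable alleles", n_mismatch)
    if not rows:
        raise ValueError("harmonize: no SNPs shared between exposure and outcome")

    exposure = exposure or TraitMeta("exposure", "quantitative", rows[0][0].n)
    outcome = outcome or TraitMeta("outcome", "quantitative", rows[0][1].n)
    return InstrumentSet(
        snp_ids=np.array([x.snp_id for x, *_ in rows], dtype=object),
        chrom=np.array([x.chrom for x, *_ in rows], dtype=object),
        pos=np.array([x.pos for x, *_ in rows], dtype=int),
        beta_x=np.array([x.beta for x, *_ in rows]),
        se_x=np.array([x.se for x, *_ in rows]),
        pval_x=np.array([x.pval for x, *_ in rows]),
        eaf_x=np.array([x.eaf for x, *_ in rows]),
        beta_y=np.array([b for *_, b, _ in rows]),
        se_y=np.array([y.se for _, y, *_ in rows]),
        pval_y=np.array([y.pval for _, y, *_ in rows]),
        eaf_y=np.array([e for *_, e in rows]),
        effect_allele=np.array([x.effect_allele for x, *_ in rows], dtype=object),
        other_allele=np.array([x.other_allele for x, *_ in rows], dtype=object),
        exposure=exposure,
        outcome=outcome,
    )
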