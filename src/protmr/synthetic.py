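"""Seeded synthetic GWAS generators with recorded ground truth.

Real proteome-wide MR studies consume plasma-pQTL summary statistics (tens
of thousands of samples, strong cis instruments) and a binary-disease GWAS
of a rare outcome (hundreds of thousands of samples, a fraction of a percent
cases, so per-allele ORs sit within about 1 +- 0.005 of unity). This module
emulates that statistical structure at two tiers and records the generating
truth so estimators can be tested for recovery:

* summary-level — :func:`simulate_instruments` and
  :func:`simulate_mediation_triplet` draw observed effects directly around
  their generative values; fast enough for calibration studies with
  thousands of replicates;
* individual-level — :func:`simulate_region_pair` simulates standardized
  genotype dosages with AR(1) correlation and summarizes marginal
  regressions, so colocalization sees realistic LD-induced correlation
  between per-SNP Bayes factors.

All generators are pure functions of their arguments including ``seed``
(one root seed; internal draws use fixed child-stream offsets), so the same
call reproduces the same dataset bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
from scipy import stats

from .gwas_io import P_FLOOR, LDMatrix, SummaryRecord, TraitMeta
from .instruments import InstrumentSet

# defaults emulate a deCODE-scale pQTL exposure cohort and a biobank-scale
# rare binary outcome (1908 cases / 461,025 controls)
N_EXPOSURE = 35_559
N_OUTCOME = 462_933
N_CASE = 1_908
N_CONTROL = 461_025
SE_EXPOSURE = 0.005  # ~ 1/sqrt(n) at the pQTL cohort scale
SE_OUTCOME = 1.5e-4  # linear-scale SE of a 0.4%-prevalence trait at n ~ 4.6e5
EXPOSURE_BETA_RANGE = (0.15, 0.5)

#: |z| needed for two-sided p < 5e-8, with a small safety margin
_Z_GWS = float(stats.norm.isf(2.5e-8)) * 1.0001

# ordered non-palindromic allele pairs (palindrome handling is exercised by
# the harmonization unit tests, not by the generators)
_ALLELE_PAIRS = [("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
                 ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G")]


@dataclass
class TruthRecord:
    """The recoverable generating truth attached to every simulated dataset."""

    seed: int
    theta_true: Any = None
    alpha: np.ndarray | None = None
    mediator_paths: list[tuple[float, float]] | None = None
    causal_snp_ids: dict | None = None
    extra: dict = field(default_factory=dict)


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(stream)])


def _two_sided_p(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2.0 * stats.norm.sf(np.abs(beta) / se)
    return np.maximum(p, P_FLOOR)


def _random_alleles(rng: np.random.Generator, k: int) -> list[tuple[str, str]]:
    idx = rng.integers(0, len(_ALLELE_PAIRS), size=k)
    return [_ALLELE_PAIRS[i] for i in idx]


# ---------------------------------------------------------------------------
# summary-level instruments
# ---------------------------------------------------------------------------

def _draw_instruments(k, theta_true, exposure_beta_range, se_x, se_y,
                      pleiotropy_model, pleiotropy_mean, pleiotropy_sd,
                      outlier_scale, seed):
    """Array core shared by the record-level and set-level generators."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if se_x <= 0 or se_y <= 0:
        raise ValueError("SE scales must be positive")
    rng = _rng(seed, 0)
    bx_true = rng.uniform(*exposure_beta_range, size=k)
    bx_obs = bx_true + rng.normal(0.0, se_x, size=k)
    # rescale so every observed exposure association is genome-wide significant
    c = max(1.0, _Z_GWS * se_x / np.min(np.abs(bx_obs)))
    bx_true *= c
    bx_obs *= c

    alpha = np.zeros(k)
    if pleiotropy_model == "balanced":
        sd = se_y * 3.0 if pleiotropy_sd is None else pleiotropy_sd
        alpha = rng.normal(0.0, sd, size=k)
    elif pleiotropy_model == "directional":
        mean = se_y * 3.0 if pleiotropy_mean is None else pleiotropy_mean
        sd = se_y if pleiotropy_sd is None else pleiotropy_sd
        alpha = rng.normal(mean, sd, size=k)
    elif pleiotropy_model == "outlier":
        scale = 10.0 * se_y if outlier_scale is None else outlier_scale
        alpha[rng.integers(0, k)] = scale
    elif pleiotropy_model != "none":
        raise ValueError(f"unknown pleiotropy_model {pleiotropy_model!r}")

    by_obs = theta_true * bx_true + alpha + rng.normal(0.0, se_y, size=k)
    eaf = rng.uniform(0.05, 0.95, size=k)
    alleles = _random_alleles(rng, k)
    return dict(bx_true=bx_true, bx_obs=bx_obs, by_obs=by_obs, alpha=alpha,
                eaf=eaf, alleles=alleles)


def simulate_instrument_set(
    k: int = 30,
    theta_true: float = 0.0,
    exposure_beta_range: tuple[float, float] = EXPOSURE_BETA_RANGE,
    se_x: float = SE_EXPOSURE,
    se_y: float = SE_OUTCOME,
    pleiotropy_model: str = "none",
    pleiotropy_mean: float | None = None,
    pleiotropy_sd: float | None = None,
    outlier_scale: float | None = None,
    n_exp: int = N_EXPOSURE,
    n_out: int = N_OUTCOME,
    seed: int = 0,
) -> tuple[InstrumentSet, TruthRecord]:
    """Directly build a harmonized :class:`InstrumentSet` plus its truth.

    This is the fast path for calibration studies (type-I error at 10,000
    seeds, estimator recovery at hundreds of seeds); it draws exactly the
    same values as :func:`simulate_instruments` at the same seed.
    """
    d = _draw_instruments(k, theta_true, exposure_beta_range, se_x, se_y,
                          pleiotropy_model, pleiotropy_mean, pleiotropy_sd,
                          outlier_scale, seed)
    snp_ids = np.array([f"rs{i + 1}" for i in range(k)], dtype=object)
    chrom = np.array([str(i % 22 + 1) for i in range(k)], dtype=object)
    # one instrument per locus, spaced far beyond the clumping window
    pos = np.array([1_000_000 + 25_000_000 * i for i in range(k)])
    meta_x = TraitMeta("sim_exposure", "quantitative", n_exp)
    meta_y = TraitMeta("sim_outcome", "binary", n_out,
                       case_fraction=N_CASE / N_OUTCOME)
    s = InstrumentSet(
        snp_ids=snp_ids, chrom=chrom, pos=pos,
        beta_x=d["bx_obs"], se_x=np.full(k, se_x),
        pval_x=_two_sided_p(d["bx_obs"], np.full(k, se_x)),
        eaf_x=d["eaf"],
        beta_y=d["by_obs"], se_y=np.full(k, se_y),
        pval_y=_two_sided_p(d["by_obs"], np.full(k, se_y)),
        eaf_y=d["eaf"],
        effect_allele=np.array([a for a, _ in d["alleles"]], dtype=object),
        other_allele=np.array([b for _, b in d["alleles"]], dtype=object),
        exposure=meta_x, outcome=meta_y,
    )
    outlier_idx = int(np.argmax(np.abs(d["alpha"]))) if pleiotropy_model == "outlier" else None
    truth = TruthRecord(seed=seed, theta_true=theta_true, alpha=d["alpha"],
                        extra={"beta_x_true": d["bx_true"],
                               "outlier_index": outlier_idx})
    return s, truth


def simulate_instruments(
    k: int = 30,
    theta_true: float = 0.0,
    exposure_beta_range: tuple[float, float] = EXPOSURE_BETA_RANGE,
    se_x: float = SE_EXPOSURE,
    se_y: float = SE_OUTCOME,
    pleiotropy_model: str = "none",
    pleiotropy_mean: float | None = None,
    pleiotropy_sd: float | None = None,
    outlier_scale: float | None = None,
    n_exp: int = N_EXPOSURE,
    n_out: int = N_OUTCOME,
    seed: int = 0,
) -> tuple[list[SummaryRecord], list[SummaryRecord], TruthRecord]:
    """Per-protein instrument-level exposure and outcome summary statistics.

    Exposure true effects are uniform on ``exposure_beta_range`` and then
    rescaled so every observed exposure p-value clears 5e-8 by construction;
    observed effects are normal around the truth with the given SE scales.
    Outcome effects follow ``theta_true * beta_x_true + alpha_i`` where the
    per-SNP pleiotropy ``alpha_i`` is zero (``none``), zero-mean normal
    (``balanced``), common-mean normal (``directional``), or zero except one
    large-effect SNP (``outlier``).
    """
    s, truth = simulate_instrument_set(
        k, theta_true, exposure_beta_range, se_x, se_y, pleiotropy_model,
        pleiotropy_mean, pleiotropy_sd, outlier_scale, n_exp, n_out, seed)
    exp_records, out_records = s.to_records()
    out_records = [
        SummaryRecord(**{**r.__dict__, "n_case": N_CASE,
                         "n_control": n_out - N_CASE})
        if n_out == N_OUTCOME else r
        for r in out_records
    ]
    return exp_records, out_records, truth


# ---------------------------------------------------------------------------
# individual-level regional pair (for colocalization)
# ---------------------------------------------------------------------------

def _marginal_scan(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-SNP simple-regression summaries of y on each column of x."""
    n = x.shape[0]
    xc = x - x.mean(axis=0)
    yc = y - y.mean()
    sxx = np.sum(xc**2, axis=0)
    beta = xc.T @ yc / sxx
    rss = np.sum(yc**2) - beta**2 * sxx
    se = np.sqrt(rss / (n - 2) / sxx)
    p = np.maximum(2.0 * stats.t.sf(np.abs(beta / se), n - 2), P_FLOOR)
    return beta, se, p


def simulate_region_pair(
    L: int = 50,
    rho: float = 0.8,
    scenario: str = "shared",
    effect_size: float = 0.15,
    n1: int = 20_000,
    n2: int = 20_000,
    seed: int = 0,
    trait_types: tuple[str, str] = ("quantitative", "quantitative"),
    prevalence: float = 0.004,
) -> tuple[list[SummaryRecord], list[SummaryRecord], LDMatrix, TruthRecord]:
    """Two traits' regional summary statistics under a colocalization scenario.

    Standardized genotype dosages with AR(1) correlation ``rho^|i-j|`` are
    simulated for two independent cohorts; each trait's phenotype adds
    ``effect_size`` times its causal SNP's dosage to unit Gaussian noise
    (binary traits dichotomize the liability at the given prevalence), and
    per-SNP marginal regressions are summarized. Scenarios: ``shared`` (one
    common causal SNP), ``distinct`` (two different SNPs), ``exposure_only``
    (trait 1 causal only), ``null`` (neither).
    """
    if L < 2:
        raise ValueError("L must be >= 2")
    if not abs(rho) < 1:
        raise ValueError("|rho| must be < 1")
    if scenario not in ("shared", "distinct", "exposure_only", "null"):
        raise ValueError(f"unknown scenario {scenario!r}")
    rng = _rng(seed, 10)
    c1 = int(rng.integers(L // 4, 3 * L // 4))
    if scenario == "shared":
        causal = {"trait1": c1, "trait2": c1}
    elif scenario == "distinct":
        # second causal SNP far enough that LD does not make it a near-copy
        others = [j for j in range(L) if abs(j - c1) > max(2, L // 8)]
        c2 = int(rng.choice(others))
        causal = {"trait1": c1, "trait2": c2}
    elif scenario == "exposure_only":
        causal = {"trait1": c1, "trait2": None}
    else:
        causal = {"trait1": None, "trait2": None}

    def _simulate_trait(n: int, c: int | None, trait_type: str, stream: int):
        r = _rng(seed, stream)
        eps = r.standard_normal((n, L))
        x = np.empty((n, L))
        x[:, 0] = eps[:, 0]
        scale = np.sqrt(1.0 - rho**2)
        for j in range(1, L):
            x[:, j] = rho * x[:, j - 1] + scale * eps[:, j]
        liability = r.standard_normal(n)
        if c is not None:
            liability = liability + effect_size * x[:, c]
        if trait_type == "binary":
            thresh = np.quantile(liability, 1.0 - prevalence)
            y = (liability > thresh).astype(float)
        else:
            y = liability
        return _marginal_scan(x, y)

    b1, s1, p1 = _simulate_trait(n1, causal["trait1"], trait_types[0], 11)
    b2, s2, p2 = _simulate_trait(n2, causal["trait2"], trait_types[1], 12)

    meta_rng = _rng(seed, 13)
    eaf = meta_rng.uniform(0.05, 0.95, size=L)
    alleles = _random_alleles(meta_rng, L)
    ids = [f"rs{j + 1}" for j in range(L)]

    def _records(b, se, p, n):
        return [
            SummaryRecord(snp_id=ids[j], chrom="1", pos=1_000_000 + 1_000 * j,
                          effect_allele=alleles[j][0], other_allele=alleles[j][1],
                          eaf=float(eaf[j]), beta=float(b[j]), se=float(se[j]),
                          pval=float(p[j]), n=n)
            for j in range(L)
        ]

    ld = LDMatrix(snp_ids=ids,
                  r=rho ** np.abs(np.subtract.outer(np.arange(L), np.arange(L))))
    truth = TruthRecord(
        seed=seed, theta_true=effect_size,
        causal_snp_ids={t: (None if c is None else ids[c]) for t, c in causal.items()},
        extra={"scenario": scenario, "rho": rho},
    )
    return _records(b1, s1, p1, n1), _records(b2, s2, p2, n2), ld, truth


# ---------------------------------------------------------------------------
# mediation triplet
# ---------------------------------------------------------------------------

def simulate_mediation_triplet(
    beta_xm: float = 0.4,
    beta_my: float = 0.5,
    theta_direct: float = 0.3,
    k_x: int = 30,
    k_m: int = 30,
    se: float = 0.005,
    n_x: int = N_EXPOSURE,
    n_m: int = 335_394,
    n_y: int = N_OUTCOME,
    seed: int = 0,
) -> tuple[list[SummaryRecord], list[SummaryRecord], list[SummaryRecord], TruthRecord]:
    """Exposure -> mediator -> outcome causal chain at summary level.

    Exposure instruments (``k_x`` SNPs) influence the mediator through
    ``beta_xm`` and the outcome through ``theta_direct + beta_xm*beta_my``;
    mediator instruments (``k_m`` disjoint SNPs) influence the outcome
    through ``beta_my`` and the exposure not at all. Returns three GWAS
    record sets — exposure, mediator, outcome — each covering all
    ``k_x + k_m`` SNPs, plus the truth (total effect
    ``theta_direct + beta_xm*beta_my``).
    """
    if k_x < 2 or k_m < 2:
        raise ValueError("k_x and k_m must be >= 2")
    rng = _rng(seed, 20)
    ids_x = [f"rsX{i + 1}" for i in range(k_x)]
    ids_m = [f"rsM{i + 1}" for i in range(k_m)]
    if set(ids_x) & set(ids_m):
        raise ValueError("exposure and mediator instrument ids overlap")

    gx = rng.uniform(*EXPOSURE_BETA_RANGE, size=k_x)  # SNP -> exposure
    gm = rng.uniform(*EXPOSURE_BETA_RANGE, size=k_m)  # SNP -> mediator

    theta_total = theta_direct + beta_xm * beta_my
    true_on_exposure = np.concatenate([gx, np.zeros(k_m)])
    true_on_mediator = np.concatenate([beta_xm * gx, gm])
    true_on_outcome = np.concatenate([theta_total * gx, beta_my * gm])

    k = k_x + k_m
    obs_x = true_on_exposure + rng.normal(0.0, se, size=k)
    obs_m = true_on_mediator + rng.normal(0.0, se, size=k)
    obs_y = true_on_outcome + rng.normal(0.0, se, size=k)
    # guarantee instrument-level genome-wide significance in the trait each
    # instrument set is selected from
    c_x = max(1.0, _Z_GWS * se / np.min(np.abs(obs_x[:k_x])))
    c_m = max(1.0, _Z_GWS * se / np.min(np.abs(obs_m[k_x:])))
    obs_x[:k_x] *= c_x
    true_on_mediator[:k_x] *= c_x
    obs_m[:k_x] *= c_x
    obs_y[:k_x] *= c_x
    obs_m[k_x:] *= c_m
    obs_y[k_x:] *= c_m

    ids = ids_x + ids_m
    eaf = rng.uniform(0.05, 0.95, size=k)
    alleles = _random_alleles(rng, k)
    se_arr = np.full(k, se)

    def _records(obs, n):
        p = _two_sided_p(obs, se_arr)
        return [
            SummaryRecord(snp_id=ids[j], chrom=str(j % 22 + 1),
                          pos=1_000_000 + 25_000_000 * (j // 22),
                          effect_allele=alleles[j][0], other_allele=alleles[j][1],
                          eaf=float(eaf[j]), beta=float(obs[j]), se=float(se),
                          pval=float(p[j]), n=n)
            for j in range(k)
        ]

    truth = TruthRecord(
        seed=seed, theta_true=theta_total,
        mediator_paths=[(beta_xm, beta_my)],
        causal_snp_ids={"exposure_instruments": ids_x,
                        "mediator_instruments": ids_m},
        extra={"theta_direct": theta_direct,
               "true_proportion": 100.0 * beta_xm * beta_my / theta_total
               if theta_total != 0 else np.nan},
    )
    return _records(obs_x, n_x), _records(obs_m, n_m), _records(obs_y, n_y), truth


# ---------------------------------------------------------------------------
# protein panel (for the end-to-end scan)
# ---------------------------------------------------------------------------

def simulate_protein_panel(
    n_proteins: int = 20,
    causal_proteins: dict[str, float] | None = None,
    k: int = 10,
    se_x: float = SE_EXPOSURE,
    se_y: float = SE_OUTCOME,
    n_exp: int = N_EXPOSURE,
    n_out: int = N_OUTCOME,
    seed: int = 0,
) -> tuple[dict[str, list[SummaryRecord]], list[SummaryRecord], LDMatrix, TruthRecord]:
    """A panel of protein exposures sharing one outcome GWAS.

    Each protein gets ``k`` independent instruments on its own disjoint SNP
    set; ``causal_proteins`` maps protein names (``P01`` ... format) to their
    nonzero causal effects, all others are null. Returns (exposures dict,
    outcome records, identity LD over all SNPs, truth).
    """
    causal_proteins = causal_proteins or {}
    names = [f"P{i + 1:02d}" for i in range(n_proteins)]
    unknown = set(causal_proteins) - set(names)
    if unknown:
        raise ValueError(f"causal proteins not in panel: {sorted(unknown)}")
    exposures: dict[str, list[SummaryRecord]] = {}
    outcome: list[SummaryRecord] = []
    all_ids: list[str] = []
    for i, name in enumerate(names):
        theta = causal_proteins.get(name, 0.0)
        exp, out, _ = simulate_instruments(
            k=k, theta_true=theta, se_x=se_x, se_y=se_y,
            n_exp=n_exp, n_out=n_out, seed=int(_rng(seed, 30 + i).integers(2**31)))
        # relabel SNPs into the protein's own namespace and locus
        prefix = f"rs{i + 1}_"
        exp = [SummaryRecord(**{**r.__dict__, "snp_id": prefix + r.snp_id,
                                "chrom": str(i % 22 + 1),
                                "pos": r.pos + 30_000_000 * (i // 22)}) for r in exp]
        out = [SummaryRecord(**{**r.__dict__, "snp_id": prefix + r.snp_id,
                                "chrom": str(i % 22 + 1),
                                "pos": r.pos + 30_000_000 * (i // 22)}) for r in out]
        exposures[name] = exp
        outcome.extend(out)
        all_ids.extend(r.snp_id for r in exp)
    ld = LDMatrix(snp_ids=all_ids, r=np.eye(len(all_ids)))
    truth = TruthRecord(seed=seed,
                        theta_true={n: causal_proteins.get(n, 0.0) for n in names})
    return exposures, outcome, ld, truth
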