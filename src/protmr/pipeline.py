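"""End-to-end orchestration of the proteome-wide MR scan.

The staged design: per-protein instrument selection (significance filter,
LD clumping, harmonization) -> primary MR estimate (Wald ratio for one
instrument, IVW otherwise) -> BH-FDR across the protein panel -> for
FDR-significant proteins, the sensitivity battery (Cochran's Q, Egger
intercept, MR-PRESSO, Steiger filtering, bidirectional MR) and Bayesian
colocalization -> mediation restricted to colocalization-supported
proteins. Every stage logs one structured line per protein; failures mark a
row "failed" rather than aborting the scan.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import shutil
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .coloc import coloc_abf, coloc_report
from .fdr import bh_fdr
from .gwas_io import (LDMatrix, SummaryRecord, TraitMeta, read_ld_matrix,
                      read_summary_stats)
from .instruments import (InstrumentSet, clump, harmonize, select_significant)
from .mediation import MediationResult, mediation_screen
from .mr import MRResult, ivw, primary_estimate, wald_ratio
from .sensitivity import (bidirectional_mr, cochran_q, egger_intercept_test,
                          mr_presso, steiger_filter)

log = logging.getLogger("protmr")

COLOC_REGION_BP = 500_000  # +-500 kb around the lead pQTL


@dataclass
class RunConfig:
    """Serializable configuration of one pipeline run."""

    exposures: dict[str, str] = field(default_factory=dict)  # protein -> file
    outcome: str = ""
    ld: str | None = None
    mediators: dict[str, str] = field(default_factory=dict)
    outcome_name: str = "outcome"
    outcome_case_fraction: float | None = None
    p_instrument: float = 5e-8
    clump_r2: float = 0.001
    clump_window_kb: float = 10_000.0
    fdr_alpha: float = 0.05
    pph4_threshold: float = 0.8
    presso_sims: int = 1000
    n_boot: int = 1000
    seed: int = 0
    out_dir: str = "protmr_run"

    def __post_init__(self) -> None:
        checks = [
            0.0 < self.p_instrument < 1.0,
            0.0 <= self.clump_r2 <= 1.0,
            self.clump_window_kb > 0,
            0.0 < self.fdr_alpha < 1.0,
            0.0 < self.pph4_threshold < 1.0,
            self.presso_sims >= 100,
        ]
        if not all(checks):
            raise ValueError("RunConfig threshold out of range")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def _trait_meta_from_records(name: str, records: Sequence[SummaryRecord],
                             case_fraction: float | None = None) -> TraitMeta:
    r = records[0]
    if r.n_case is not None and r.n_control is not None:
        return TraitMeta(name, "binary", r.n, case_fraction=r.n_case / r.n)
    if case_fraction is not None:
        return TraitMeta(name, "binary", r.n, case_fraction=case_fraction)
    return TraitMeta(name, "quantitative", r.n)


def _child_seed(seed: int, idx: int) -> int:
    return int(np.random.default_rng([seed, idx]).integers(2**31))


# ---------------------------------------------------------------------------
# scan core (in-memory API)
# ---------------------------------------------------------------------------

def protein_scan(
    exposures: Mapping[str, Sequence[SummaryRecord]],
    outcome_records: Sequence[SummaryRecord],
    ld: LDMatrix | None = None,
    config: RunConfig | None = None,
    outcome_meta: TraitMeta | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Run the per-protein scan on in-memory records.

    Returns the scan table (one row per protein, sorted by name) and a
    details dict holding the harmonized instrument sets and per-protein
    diagnostic objects. Proteins are processed in sorted-name order with
    per-protein child seeds, so the result is independent of input order
    and deterministic given the config seed.
    """
    config = config or RunConfig()
    outcome_meta = outcome_meta or _trait_meta_from_records(
        config.outcome_name, outcome_records, config.outcome_case_fraction)

    rows: list[dict] = []
    details: dict = {"sets": {}, "sensitivity": {}, "coloc": {}}
    names = sorted(exposures)
    for i, name in enumerate(names):
        row: dict = {"protein": name, "status": "ok"}
        try:
            exp_records = list(exposures[name])
            sel = select_significant(exp_records, config.p_instrument)
            if not sel:
                raise ValueError("no genome-wide-significant instruments")
            if ld is not None:
                sel = clump(sel, ld, config.clump_r2, config.clump_window_kb)
            exp_meta = _trait_meta_from_records(name, exp_records)
            iset = harmonize(sel, outcome_records,
                             exposure=exp_meta, outcome=outcome_meta)
            est = primary_estimate(iset)
            details["sets"][name] = iset
            row.update(n_snp=iset.n_snp, method=est.method, beta=est.beta,
                       se=est.se, pval=est.pval, or_point=est.or_point,
                       or_low=est.or_low, or_high=est.or_high)
            log.info("scan %s: %s beta=%.4g p=%.3g (%d SNPs)",
                     name, est.method, est.beta, est.pval, iset.n_snp)
        except (ValueError, ArithmeticError) as exc:
            row.update(status="failed", reason=str(exc))
            log.warning("scan %s failed: %s", name, exc)
        rows.append(row)

    df = pd.DataFrame(rows)
    df["qval"] = np.nan
    df["fdr_significant"] = False
    df["colocalized"] = False
    ok = df["status"] == "ok"
    if ok.any():
        fdr_table = bh_fdr(df.loc[ok, "pval"].to_numpy(),
                           alpha=config.fdr_alpha,
                           ids=df.loc[ok, "protein"].tolist())
        df.loc[ok, "qval"] = fdr_table["qval"].to_numpy()
        df.loc[ok, "fdr_significant"] = fdr_table["significant"].to_numpy()

    # sensitivity battery + coloc only for FDR-significant proteins
    for i, name in enumerate(names):
        if name not in details["sets"]:
            continue
        mask = df["protein"] == name
        if not bool(df.loc[mask, "fdr_significant"].iloc[0]):
            continue
        iset: InstrumentSet = details["sets"][name]
        seed_i = _child_seed(config.seed, i)
        sens: dict = {}
        if iset.n_snp >= 2:
            het = cochran_q(iset)
            sens["heterogeneity"] = het
            df.loc[mask, "q_pval"] = het.pval
        if iset.n_snp >= 3:
            _, _, egger_p = egger_intercept_test(iset)
            df.loc[mask, "egger_intercept_pval"] = egger_p
        if iset.n_snp >= 4:
            presso = mr_presso(iset, n_sim=config.presso_sims, seed=seed_i)
            sens["presso"] = presso
            df.loc[mask, "presso_global_pval"] = presso.global_pval
            df.loc[mask, "presso_n_outliers"] = len(presso.outlier_indices)
        steiger, filtered = steiger_filter(iset)
        sens["steiger"] = steiger
        df.loc[mask, "steiger_direction"] = bool(steiger.overall_direction_true)
        if filtered.n_snp >= 1:
            post = primary_estimate(filtered)
            df.loc[mask, "post_steiger_pval"] = post.pval
        # reverse orientation: outcome SNPs as instruments for the protein,
        # Steiger-filtered so instruments explaining more variance in the
        # protein than in the disease are not misread as reverse causation
        rev_sel = select_significant(list(outcome_records), config.p_instrument)
        reverse = None
        if rev_sel:
            try:
                if ld is not None and all(r.snp_id in ld for r in rev_sel):
                    rev_sel = clump(rev_sel, ld, config.clump_r2,
                                    config.clump_window_kb)
                reverse = harmonize(rev_sel, list(exposures[name]),
                                    exposure=iset.outcome, outcome=iset.exposure)
                _, reverse = steiger_filter(reverse)
                if reverse.n_snp == 0:
                    reverse = None
            except ValueError:
                reverse = None
        bidir = bidirectional_mr(iset, reverse)
        sens["bidirectional"] = bidir
        df.loc[mask, "reverse_pval"] = (np.nan if bidir.reverse is None
                                        else bidir.reverse.pval)
        df.loc[mask, "reverse_causation"] = bidir.reverse_causation_flag
        details["sensitivity"][name] = sens

        # colocalization over the +-500 kb window around the lead pQTL
        # (lead chosen by |z| -- p-values underflow for very strong pQTLs)
        lead_idx = int(np.argmax(np.abs(iset.beta_x) / iset.se_x))
        lead = iset.snp_ids[lead_idx]
        lead_chrom = iset.chrom[lead_idx]
        lead_pos = int(iset.pos[lead_idx])
        region_x = [r for r in exposures[name]
                    if r.chrom == lead_chrom and abs(r.pos - lead_pos) <= COLOC_REGION_BP]
        region_y = [r for r in outcome_records
                    if r.chrom == lead_chrom and abs(r.pos - lead_pos) <= COLOC_REGION_BP]
        try:
            cres = coloc_abf(region_x, region_y,
                             trait_types=("quantitative",
                                          outcome_meta.trait_type))
            details["coloc"][name] = cres
            df.loc[mask, ["pph0", "pph1", "pph2", "pph3", "pph4"]] = (
                cres.pph0, cres.pph1, cres.pph2, cres.pph3, cres.pph4)
            df.loc[mask, "colocalized"] = bool(cres.pph4 >= config.pph4_threshold)
            log.info("coloc %s: lead %s, PPH4=%.3f", name, lead, cres.pph4)
        except (ValueError, ArithmeticError) as exc:
            log.warning("coloc %s failed: %s", name, exc)
    return df, details


def volcano_table(scan: pd.DataFrame) -> pd.DataFrame:
    ok = scan[scan["status"] == "ok"]
    return pd.DataFrame({"protein": ok["protein"], "beta": ok["beta"],
                         "neg_log10_q": -np.log10(ok["qval"])})


def forest_table(scan: pd.DataFrame) -> pd.DataFrame:
    ok = scan[scan["status"] == "ok"]
    return ok[["protein", "n_snp", "or_point", "or_low", "or_high", "pval", "qval"]]


# ---------------------------------------------------------------------------
# mediation stage
# ---------------------------------------------------------------------------

def mediation_stage(
    exposures: Mapping[str, Sequence[SummaryRecord]],
    outcome_records: Sequence[SummaryRecord],
    mediators: Mapping[str, Sequence[SummaryRecord]],
    scan: pd.DataFrame,
    details: dict,
    config: RunConfig,
) -> tuple[list[MediationResult], list]:
    """Two-step mediation for colocalization-supported proteins.

    Step 1 re-uses each protein's instruments against the mediator GWAS;
    step 2 instruments the mediator with its own genome-wide-significant
    SNPs, excluding any SNP that is itself a pQTL instrument (significant in
    any scanned exposure), then estimates mediator -> outcome by IVW.
    """
    chosen = scan.loc[scan.get("colocalized", False) == True, "protein"].tolist()  # noqa: E712
    totals: dict[str, MRResult] = {}
    step1: dict[tuple[str, str], MRResult] = {}
    step2: dict[str, MRResult] = {}

    pqtl_ids = set()
    for recs in exposures.values():
        pqtl_ids.update(r.snp_id for r in recs if r.pval < config.p_instrument)

    outcome_meta = _trait_meta_from_records(config.outcome_name, outcome_records,
                                            config.outcome_case_fraction)
    for med_name, med_records in sorted(mediators.items()):
        med_records = list(med_records)
        med_meta = _trait_meta_from_records(med_name, med_records)
        sel = [r for r in select_significant(med_records, config.p_instrument)
               if r.snp_id not in pqtl_ids]
        if not sel:
            log.warning("mediator %s: no instruments after pQTL exclusion", med_name)
            continue
        try:
            mset = harmonize(sel, outcome_records,
                             exposure=med_meta, outcome=outcome_meta)
            step2[med_name] = primary_estimate(mset)
        except ValueError as exc:
            log.warning("mediator %s -> outcome failed: %s", med_name, exc)

    for name in chosen:
        iset = details["sets"].get(name)
        if iset is None:
            continue
        mask = scan["protein"] == name
        totals[name] = ivw(iset) if iset.n_snp >= 2 else wald_ratio(iset)
        exp_sel = select_significant(list(exposures[name]), config.p_instrument)
        for med_name, med_records in sorted(mediators.items()):
            try:
                s1_set = harmonize(exp_sel, list(med_records),
                                   exposure=iset.exposure,
                                   outcome=_trait_meta_from_records(med_name, list(med_records)))
                step1[(name, med_name)] = primary_estimate(s1_set)
            except ValueError as exc:
                log.info("step1 %s->%s failed: %s", name, med_name, exc)

    return mediation_screen(totals, step1, step2, alpha=0.05)


# ---------------------------------------------------------------------------
# file-level entry points
# ---------------------------------------------------------------------------

def _load_inputs(config: RunConfig):
    exposures = {name: read_summary_stats(path)
                 for name, path in config.exposures.items()}
    outcome = read_summary_stats(config.outcome)
    ld = read_ld_matrix(config.ld) if config.ld else None
    mediators = {name: read_summary_stats(path)
                 for name, path in config.mediators.items()}
    return exposures, outcome, ld, mediators


def run_protein_scan(config: RunConfig) -> pd.DataFrame:
    """File-based scan: load the configured inputs and run :func:`protein_scan`."""
    exposures, outcome, ld, _ = _load_inputs(config)
    scan, _ = protein_scan(exposures, outcome, ld, config)
    return scan


def run_full_pipeline(config: RunConfig, force: bool = False) -> Path:
    """Execute the complete study flow and write all output tables.

    Writes ``scan.tsv``, ``volcano.tsv``, ``forest.tsv``, ``coloc.tsv``,
    ``mediation.tsv`` (when mediators are configured), ``run.json`` and
    ``run.log`` into ``config.out_dir``. Refuses to overwrite an existing
    run directory unless ``force``.
    """
    out = Path(config.out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"{out} exists; pass force=True to overwrite")
    if out.exists() and force:
        shutil.rmtree(out)
    out.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        exposures, outcome, ld, mediators = _load_inputs(config)
        scan, details = protein_scan(exposures, outcome, ld, config)
        scan.to_csv(out / "scan.tsv", sep="\t", index=False, float_format="%.12g")
        volcano_table(scan).to_csv(out / "volcano.tsv", sep="\t", index=False,
                                   float_format="%.12g")
        forest_table(scan).to_csv(out / "forest.tsv", sep="\t", index=False,
                                  float_format="%.12g")
        if details["coloc"]:
            coloc_report(details["coloc"], config.pph4_threshold).to_csv(
                out / "coloc.tsv", sep="\t", index=False, float_format="%.12g")

        n_med = 0
        if mediators:
            med_results, skipped = mediation_stage(exposures, outcome, mediators,
                                                   scan, details, config)
            if med_results:
                rows = [{
                    "exposure": m.exposure, "mediator": m.mediator,
                    "total_beta": m.total.beta, "total_se": m.total.se,
                    "step1_beta": m.step1.beta, "step2_beta": m.step2.beta,
                    "indirect_beta": m.indirect_beta, "indirect_se": m.indirect_se,
                    "direct_beta": m.direct_beta,
                    "proportion_pct": round(m.proportion, 2),
                    "proportion_se_pct": m.proportion_se,
                    "warning": m.warning,
                } for m in med_results]
                pd.DataFrame(rows).to_csv(out / "mediation.tsv", sep="\t",
                                          index=False, float_format="%.12g")
                n_med = len(med_results)
        else:
            log.warning("no mediator files configured; mediation stage skipped")

        meta = {
            "protmr_version": __version__,
            "python": sys.version.split()[0],
            "numpy": np.__version__,
            "seed": config.seed,
            "config": dataclasses.asdict(config),
            "n_proteins": len(exposures),
            "n_fdr_significant": int(scan["fdr_significant"].sum()),
            "n_colocalized": int(scan["colocalized"].sum()),
            "n_mediation_results": n_med,
        }
        with open(out / "run.json", "w") as fh:
            json.dump(meta, fh, indent=2, sort_keys=True)
    finally:
        log.removeHandler(handler)
        handler.close()
    return out
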