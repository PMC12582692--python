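"""Reading, validating, and writing GWAS summary statistics and LD matrices.

GWAS summary statistics arrive as delimited text, one row per SNP, with a
header. This module defines the canonical in-memory records used throughout
the package (:class:`SummaryRecord`, :class:`TraitMeta`, :class:`LDMatrix`),
validates inputs against the per-SNP invariants, and writes result tables in
a deterministic, round-trippable tab-separated format.

Conventions
-----------
* Coordinates are 1-based, inclusive (the GWAS summary-statistics convention).
* Only single-base A/C/G/T alleles are supported; rows with indels or other
  allele codes are dropped and counted in the run log.
* Input delimiter is auto-detected among tab, comma, and whitespace; all
  output is tab-separated.
* p-values of exactly zero are clamped to 1e-300 with a warning (downstream
  Steiger filtering converts p to a correlation and needs p > 0).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger("protmr")

VALID_BASES = frozenset("ACGT")
P_FLOOR = 1e-300

#: canonical column names for summary-statistics files
STANDARD_COLUMNS = (
    "SNP", "CHR", "POS", "EA", "OA", "EAF", "BETA", "SE", "P", "N",
    "N_CASE", "N_CONTROL",
)
MANDATORY_COLUMNS = STANDARD_COLUMNS[:10]


@dataclass(frozen=True)
class SummaryRecord:
    """One SNP's association with one trait.

    ``beta`` is the per-effect-allele effect (log-odds for binary traits,
    SD units for quantitative traits); ``eaf`` is the effect-allele
    frequency.
    """

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    pval: float
    n: int
    n_case: int | None = None
    n_control: int | None = None

    def invalid_reason(self) -> str | None:
        """Return a human-readable reason this record violates an invariant,
        or ``None`` if it is valid."""
        if self.effect_allele not in VALID_BASES or self.other_allele not in VALID_BASES:
            return "allele not a single A/C/G/T base"
        if self.effect_allele == self.other_allele:
            return "effect and other allele identical"
        if not (self.se > 0) or not math.isfinite(self.se):
            return "non-positive or non-finite standard error"
        if not (0.0 < self.pval <= 1.0):
            return "p-value outside (0, 1]"
        if not (0.0 <= self.eaf <= 1.0):
            return "EAF outside [0, 1]"
        if self.pos < 1:
            return "position < 1"
        if not math.isfinite(self.beta):
            return "non-finite beta"
        if self.n_case is not None and self.n_control is not None:
            if self.n_case + self.n_control != self.n:
                return "n_case + n_control != n"
        return None


@dataclass(frozen=True)
class TraitMeta:
    """Metadata for one trait's GWAS: name, type, and sample size."""

    trait_name: str
    trait_type: str  # "quantitative" or "binary"
    sample_size: int
    case_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.trait_type not in ("quantitative", "binary"):
            raise ValueError(f"unknown trait_type {self.trait_type!r}")
        if self.trait_type == "binary":
            if self.case_fraction is None or not (0.0 < self.case_fraction < 1.0):
                raise ValueError("binary trait requires case_fraction in (0, 1)")
        elif self.case_fraction is not None:
            raise ValueError("case_fraction only meaningful for binary traits")


@dataclass
class LDMatrix:
    """Pairwise LD correlations (r, not r^2) for an ordered SNP panel."""

    snp_ids: list[str]
    r: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        m = len(self.snp_ids)
        if self.r.shape != (m, m):
            raise ValueError(f"LD matrix shape {self.r.shape} does not match {m} SNP ids")
        if np.max(np.abs(self.r - self.r.T)) > 1e-8:
            raise ValueError("LD matrix is not symmetric (tolerance 1e-8)")
        if np.max(np.abs(np.diag(self.r) - 1.0)) > 1e-8:
            raise ValueError("LD matrix diagonal is not 1")
        if np.max(np.abs(self.r)) > 1.0 + 1e-8:
            raise ValueError("LD correlations must lie in [-1, 1]")
        self._index = {s: i for i, s in enumerate(self.snp_ids)}
        if len(self._index) != m:
            raise ValueError("duplicate SNP ids in LD matrix")

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._index

    def r2(self, a: str, b: str) -> float:
        """Squared correlation between two SNPs."""
        return float(self.r[self._index[a], self._index[b]] ** 2)


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def _detect_sep(path: Path) -> str | None:
    with open(path) as fh:
        header = fh.readline()
    if "\t" in header:
        return "\t"
    if "," in header:
        return ","
    return r"\s+"


def read_summary_stats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    trait: TraitMeta | None = None,
) -> list[SummaryRecord]:
    """Read a delimited summary-statistics file into validated records.

    Parameters
    ----------
    path
        Delimited text file with a header row.
    column_map
        Optional mapping from canonical names (``SNP``, ``CHR``, ``POS``,
        ``EA``, ``OA``, ``EAF``, ``BETA``, ``SE``, ``P``, ``N``, and
        optionally ``N_CASE``/``N_CONTROL``) to the file's column names.
    trait
        Optional trait metadata; when given and the file lacks an ``N``
        column, ``trait.sample_size`` fills it.

    Rows violating the per-SNP invariants (zero SE, out-of-range EAF or p,
    non-ACGT alleles, ...) are dropped and counted in the log. Alleles are
    upper-cased; p-values of exactly 0 are clamped to 1e-300.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_detect_sep(path), engine="python")
    colmap = dict(column_map or {})
    rename = {}
    for canonical in STANDARD_COLUMNS:
        src = colmap.get(canonical, canonical)
        if src in df.columns:
            rename[src] = canonical
    df = df.rename(columns=rename)
    if "N" not in df.columns and trait is not None:
        df["N"] = trait.sample_size
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing mandatory column(s): {', '.join(missing)}")

    records: list[SummaryRecord] = []
    n_dropped = 0
    n_clamped = 0
    for row in df.itertuples(index=False):
        d = row._asdict()
        pval = float(d["P"])
        if pval == 0.0:
            pval = P_FLOOR
            n_clamped += 1
        try:
            rec = SummaryRecord(
                snp_id=str(d["SNP"]),
                chrom=str(d["CHR"]),
                pos=int(d["POS"]),
                effect_allele=str(d["EA"]).upper(),
                other_allele=str(d["OA"]).upper(),
                eaf=float(d["EAF"]),
                beta=float(d["BETA"]),
                se=float(d["SE"]),
                pval=pval,
                n=int(d["N"]),
                n_case=None if pd.isna(d.get("N_CASE", None)) else int(d["N_CASE"]),
                n_control=None if pd.isna(d.get("N_CONTROL", None)) else int(d["N_CONTROL"]),
            )
        except (TypeError, ValueError):
            n_dropped += 1
            continue
        reason = rec.invalid_reason()
        if reason is not None:
            log.debug("dropping %s: %s", rec.snp_id, reason)
            n_dropped += 1
            continue
        records.append(rec)

    if n_clamped:
        log.warning("%s: clamped %d zero p-value(s) to %.0e", path.name, n_clamped, P_FLOOR)
    if n_dropped:
        log.info("%s: dropped %d invalid row(s)", path.name, n_dropped)
    if not records:
        raise ValueError(f"{path}: no valid summary-statistic rows")
    return records


def validate_records(records: Iterable[SummaryRecord]) -> tuple[list[SummaryRecord], int]:
    """Split records into (valid records, number dropped)."""
    records = list(records)
    kept = [r for r in records if r.invalid_reason() is None]
    return kept, len(records) - len(kept)


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def _flatten(obj: Any) -> dict[str, Any]:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        d = dataclasses.asdict(obj)
    elif isinstance(obj, Mapping):
        d = dict(obj)
    else:
        raise TypeError(f"cannot tabulate object of type {type(obj).__name__}")
    out: dict[str, Any] = {}
    for k, v in d.items():
        if isinstance(v, Mapping):
            for k2 in sorted(v):
                out[f"{k}_{k2}"] = v[k2]
        elif isinstance(v, (list, tuple, np.ndarray)):
            out[k] = json.dumps(np.asarray(v).tolist())
        else:
            out[k] = v
    return out


def write_results_table(items: Sequence[Any], path: str | Path) -> None:
    """Write any homogeneous list of result dataclasses (or dicts) as TSV.

    Column order follows dataclass field order (nested maps are expanded into
    ``field_key`` columns, sorted); floats are written with 12 significant
    digits so a round-trip read reproduces values to at least 10 significant
    digits.
    """
    if len(items) == 0:
        raise ValueError("refusing to write an empty results table")
    rows = [_flatten(x) for x in items]
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_results_table(path: str | Path) -> pd.DataFrame:
    """Read back a table written by :func:`write_results_table`."""
    return pd.read_csv(path, sep="\t")


def records_to_frame(records: Sequence[SummaryRecord]) -> pd.DataFrame:
    """Summary records as a DataFrame with the standard column names."""
    df = pd.DataFrame(
        {
            "SNP": [r.snp_id for r in records],
            "CHR": [r.chrom for r in records],
            "POS": [r.pos for r in records],
            "EA": [r.effect_allele for r in records],
            "OA": [r.other_allele for r in records],
            "EAF": [r.eaf for r in records],
            "BETA": [r.beta for r in records],
            "SE": [r.se for r in records],
            "P": [r.pval for r in records],
            "N": [r.n for r in records],
        }
    )
    if any(r.n_case is not None for r in records):
        df["N_CASE"] = [r.n_case for r in records]
        df["N_CONTROL"] = [r.n_control for r in records]
    return df


def write_summary_stats(records: Sequence[SummaryRecord], path: str | Path) -> None:
    """Write summary records in the standard tab-separated layout."""
    records_to_frame(records).to_csv(path, sep="\t", index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# LD matrices
# ---------------------------------------------------------------------------

def read_ld_matrix(path: str | Path) -> LDMatrix:
    """Read an LD correlation matrix whose first row and column are SNP ids."""
    path = Path(path)
    df = pd.read_csv(path, sep=_detect_sep(path), engine="python", index_col=0)
    if df.shape[0] != df.shape[1]:
        raise ValueError(f"{path}: LD matrix is not square ({df.shape[0]}x{df.shape[1]})")
    if list(df.index.astype(str)) != list(df.columns.astype(str)):
        raise ValueError(f"{path}: LD matrix row and column ids disagree")
    return LDMatrix(snp_ids=[str(s) for s in df.index], r=df.to_numpy(dtype=float))


def write_ld_matrix(ld: LDMatrix, path: str | Path) -> None:
    pd.DataFrame(ld.r, index=ld.snp_ids, columns=ld.snp_ids).to_csv(
        path, sep="\t", float_format="%.12g"
    )
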