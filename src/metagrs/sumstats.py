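"""Reading, QC filtering, allele harmonization and weight-table I/O.

GWAS summary statistics are carried as a :class:`pandas.DataFrame` with
canonical columns ``chrom, pos, id, ea, oa, beta, se, p, eaf`` (and
optionally ``info``), wrapped in :class:`SumStats` together with a trait
label.  Per-SNP score weights travel as a DataFrame with columns
``chrom, pos, id, ea, oa, weight``.

Variant identity for joins is ``(chrom, pos)`` with allele
reconciliation, not rsID, because rsIDs are unreliable across summary
statistic sources.  Coordinates are 1-based throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

#: canonical column order of a summary-statistic table
SUMSTAT_COLUMNS = ["chrom", "pos", "id", "ea", "oa", "beta", "se", "p", "eaf"]

#: default mapping from canonical names to on-disk TSV column headers
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "chrom": "CHR",
    "pos": "POS",
    "id": "ID",
    "ea": "EA",
    "oa": "OA",
    "beta": "BETA",
    "se": "SE",
    "p": "P",
    "eaf": "EAF",
    "info": "INFO",
}

_VALID_ALLELES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_AMBIGUOUS_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


@dataclass
class SumStats:
    """One trait's GWAS summary statistics.

    ``df`` holds one row per variant; ``beta`` is the per-effect-allele
    effect size (log-odds or linear scale), ``eaf`` the effect-allele
    frequency.
    """

    df: pd.DataFrame
    trait: str = ""

    def __post_init__(self) -> None:
        missing = [c for c in SUMSTAT_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValidationError(f"summary statistics missing columns: {missing}")
        key = self.df[["chrom", "pos", "ea", "oa"]]
        if key.duplicated().any():
            raise ValidationError("duplicate (chrom, pos, ea, oa) rows in summary statistics")
        p = self.df["p"].to_numpy(dtype=float)
        if np.any((p < 0) | (p > 1)):
            raise ValidationError("p-values outside [0, 1]")
        se = self.df["se"].to_numpy(dtype=float)
        if np.any(se[np.isfinite(se)] <= 0):
            raise ValidationError("non-positive standard errors")

    def __len__(self) -> int:
        return len(self.df)


@dataclass(frozen=True)
class QcFilterSpec:
    """Variant QC thresholds: rows strictly below either threshold are removed."""

    info_min: float = 0.0
    maf_min: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.info_min <= 1.0):
            raise ValidationError(f"info_min must be in [0, 1], got {self.info_min}")
        if not (0.0 <= self.maf_min <= 0.5):
            raise ValidationError(f"maf_min must be in [0, 0.5], got {self.maf_min}")


def read_sumstats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    trait: str = "",
    sep: str = "\t",
) -> SumStats:
    """Read a summary-statistic TSV, coercing types and dropping bad rows.

    Rows whose mandatory fields fail numeric coercion (e.g. ``NA``
    p-values) are rejected; the reject count is logged.  A file missing
    a mandatory mapped column raises :class:`FormatError`; a file with
    zero valid rows raises :class:`FormatError`.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    raw = pd.read_csv(path, sep=sep, dtype=str)
    mandatory = SUMSTAT_COLUMNS
    missing = [cmap[c] for c in mandatory if cmap[c] not in raw.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory columns {missing}")

    out = pd.DataFrame(index=raw.index)
    out["chrom"] = raw[cmap["chrom"]].astype(str)
    out["id"] = raw[cmap["id"]].astype(str)
    out["ea"] = raw[cmap["ea"]].astype(str).str.upper()
    out["oa"] = raw[cmap["oa"]].astype(str).str.upper()
    out["pos"] = pd.to_numeric(raw[cmap["pos"]], errors="coerce")
    for c in ("beta", "se", "p", "eaf"):
        out[c] = pd.to_numeric(raw[cmap[c]], errors="coerce")
    has_info = cmap["info"] in raw.columns
    if has_info:
        out["info"] = pd.to_numeric(raw[cmap["info"]], errors="coerce")

    ok = (
        out[["pos", "beta", "se", "p", "eaf"]].notna().all(axis=1)
        & out["ea"].isin(_VALID_ALLELES)
        & out["oa"].isin(_VALID_ALLELES)
        & (out["ea"] != out["oa"])
        & (out["pos"] >= 1)
        & out["p"].between(0, 1)
        & (out["se"] > 0)
    )
    n_rejected = int((~ok).sum())
    if n_rejected:
        logger.info("read_sumstats(%s): rejected %d malformed rows", path, n_rejected)
    out = out.loc[ok].reset_index(drop=True)
    if len(out) == 0:
        raise FormatError(f"{path}: no valid rows after type coercion")
    out["pos"] = out["pos"].astype(np.int64)
    return SumStats(out, trait=trait)


def apply_variant_qc(table: SumStats, spec: QcFilterSpec) -> SumStats:
    """Remove variants with MAF or imputation INFO strictly below threshold.

    The filter removes rows with ``min(eaf, 1-eaf) < maf_min`` or
    ``info < info_min``; rows exactly at a threshold pass.  Row order is
    preserved and the operation is idempotent.
    """
    df = table.df
    keep = pd.Series(True, index=df.index)
    if spec.maf_min > 0:
        if df["eaf"].isna().any():
            raise ValidationError("MAF filtering requires eaf for every row")
        maf = np.minimum(df["eaf"], 1.0 - df["eaf"])
        keep &= maf >= spec.maf_min
    if spec.info_min > 0:
        if "info" not in df.columns or df["info"].isna().any():
            raise ValidationError("INFO filtering requires an info column without missing values")
        keep &= df["info"] >= spec.info_min
    return SumStats(df.loc[keep].reset_index(drop=True), trait=table.trait)


@dataclass
class HarmonizationReport:
    """Per-category counts from :func:`harmonize_alleles`."""

    n_match: int = 0
    n_swapped: int = 0
    n_strand_flipped: int = 0
    n_dropped_ambiguous: int = 0
    n_dropped_unmatched: int = 0


def harmonize_alleles(
    table: SumStats, reference: pd.DataFrame
) -> tuple[SumStats, HarmonizationReport]:
    """Orient summary-statistic rows onto a reference allele frame.

    ``reference`` needs columns ``chrom, pos, ea, oa`` and must be
    unique by ``(chrom, pos)``.  Matching is positional; for each
    matched row: a same-allele match is kept unchanged, a swapped
    effect/other match flips the sign of ``beta`` (and ``eaf`` to
    ``1-eaf``) and swaps the alleles, a strand-complement match is
    complemented first.  Strand-ambiguous variants (A/T, C/G) and rows
    without a positional match are dropped and counted — dropping
    ambiguous palindromic variants is the conservative default since
    their strand cannot be resolved from alleles alone.
    """
    ref = reference
    if ref[["chrom", "pos"]].duplicated().any():
        raise ValidationError("reference variants must be unique by (chrom, pos)")
    ref_idx = ref.set_index(["chrom", "pos"])[["ea", "oa"]]

    df = table.df.copy()
    report = HarmonizationReport()
    keep_rows = []
    for i, row in df.iterrows():
        pair = (row["ea"], row["oa"])
        if pair in _AMBIGUOUS_PAIRS:
            report.n_dropped_ambiguous += 1
            continue
        try:
            ref_ea, ref_oa = ref_idx.loc[(row["chrom"], row["pos"])]
        except KeyError:
            report.n_dropped_unmatched += 1
            continue
        ea, oa = pair
        cea, coa = _COMPLEMENT[ea], _COMPLEMENT[oa]
        if (ea, oa) == (ref_ea, ref_oa):
            report.n_match += 1
        elif (ea, oa) == (ref_oa, ref_ea):
            df.at[i, "beta"] = -row["beta"]
            df.at[i, "eaf"] = 1.0 - row["eaf"]
            df.at[i, "ea"], df.at[i, "oa"] = ref_ea, ref_oa
            report.n_swapped += 1
        elif (cea, coa) == (ref_ea, ref_oa):
            df.at[i, "ea"], df.at[i, "oa"] = ref_ea, ref_oa
            report.n_strand_flipped += 1
        elif (cea, coa) == (ref_oa, ref_ea):
            df.at[i, "beta"] = -row["beta"]
            df.at[i, "eaf"] = 1.0 - row["eaf"]
            df.at[i, "ea"], df.at[i, "oa"] = ref_ea, ref_oa
            report.n_strand_flipped += 1
        else:
            report.n_dropped_unmatched += 1
            continue
        keep_rows.append(i)
    out = df.loc[keep_rows].reset_index(drop=True)
    if (report.n_dropped_ambiguous or report.n_dropped_unmatched):
        logger.info(
            "harmonize_alleles: dropped %d ambiguous, %d unmatched of %d rows",
            report.n_dropped_ambiguous, report.n_dropped_unmatched, len(table.df),
        )
    return SumStats(out, trait=table.trait), report


WEIGHT_COLUMNS = ["chrom", "pos", "id", "ea", "oa", "weight"]


def _validate_weights(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ("id", "ea", "weight") if c not in df.columns]
    if missing:
        raise FormatError(f"weight table missing columns: {missing}")
    if not np.all(np.isfinite(df["weight"].to_numpy(dtype=float))):
        raise FormatError("weight table contains non-finite weights")
    key_cols = ["chrom", "pos", "ea", "oa"] if "chrom" in df.columns else ["id", "ea"]
    if df[key_cols].duplicated().any():
        raise FormatError("duplicate variant keys in weight table")
    return df


def write_snp_weights(table: pd.DataFrame, path: str | Path) -> None:
    """Write a per-SNP weight table as TSV.

    The core columns ``ID, EA, WEIGHT`` follow the layout of published
    per-SNP score files; ``CHR, POS, OA`` are written too when present
    so that the round trip is lossless.
    """
    df = _validate_weights(table)
    out = pd.DataFrame()
    if "chrom" in df.columns:
        out["CHR"] = df["chrom"]
        out["POS"] = df["pos"]
    out["ID"] = df["id"]
    out["EA"] = df["ea"]
    if "oa" in df.columns:
        out["OA"] = df["oa"]
    out["WEIGHT"] = df["weight"].map(lambda w: repr(float(w)))
    out.to_csv(path, sep="\t", index=False)


def read_snp_weights(path: str | Path) -> pd.DataFrame:
    """Read a TSV weight table written by :func:`write_snp_weights`.

    Accepts both the full six-column dialect and the minimal
    ``ID, EA, WEIGHT`` layout.  Duplicate variant keys raise
    :class:`FormatError`.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str)
    need = [c for c in ("ID", "EA", "WEIGHT") if c not in raw.columns]
    if need:
        raise FormatError(f"{path}: missing weight columns {need}")
    df = pd.DataFrame()
    if "CHR" in raw.columns and "POS" in raw.columns:
        df["chrom"] = raw["CHR"].astype(str)
        df["pos"] = pd.to_numeric(raw["POS"]).astype(np.int64)
    df["id"] = raw["ID"].astype(str)
    df["ea"] = raw["EA"].astype(str)
    if "OA" in raw.columns:
        df["oa"] = raw["OA"].astype(str)
    df["weight"] = pd.to_numeric(raw["WEIGHT"], errors="raise").astype(float)
    return _validate_weights(df)
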