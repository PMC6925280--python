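"""Single-trait genomic risk score construction.

A GRS is built from GWAS summary statistics by greedy LD pruning
(remove one of every locally correlated variant pair) followed by
p-value or FDR thresholding; the retained per-allele effect sizes are
the score weights.  Candidate scores over a grid of r² thresholds are
compared by the magnitude of their hazard ratio on a tuning cohort and
the strongest is kept, giving one representative GRS per trait.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average as _hc_average, leaves_list
from scipy.spatial.distance import squareform
from scipy.stats import t as t_dist
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateError, EmptyOverlapError, ValidationError
from .genotypes import GenotypeMatrix
from .sumstats import SumStats

__all__ = [
    "PruneParams",
    "GrsWeights",
    "ScoreVector",
    "CandidateEntry",
    "greedy_ld_prune",
    "bh_fdr",
    "threshold_variants",
    "score_samples",
    "standardize",
    "select_candidate",
    "build_candidate_grid",
    "component_correlation",
]


@dataclass(frozen=True)
class PruneParams:
    """Greedy LD-pruning parameters (kb window, variant step, r² ceiling)."""

    window_kb: int = 250
    step: int = 1
    r2_max: float = 0.2

    def __post_init__(self) -> None:
        if not (0.0 <= self.r2_max <= 1.0):
            raise ValidationError(f"r2_max must be in [0, 1], got {self.r2_max}")
        if self.window_kb < 1:
            raise ValidationError("window_kb must be >= 1")
        if self.step < 1:
            raise ValidationError("step must be >= 1")


#: default r²-threshold grid for candidate scores
DEFAULT_R2_GRID = (0.1, 0.2, 0.5, 0.8)


@dataclass
class GrsWeights:
    """A single-trait score: the retained variants and their weights."""

    trait: str
    df: pd.DataFrame  # columns chrom, pos, id, ea, oa, weight

    def __post_init__(self) -> None:
        if self.df[["chrom", "pos", "ea", "oa"]].duplicated().any():
            raise ValidationError("duplicate variants in GRS weights")

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class ScoreVector:
    """Per-sample raw scores plus a stored standardization transform.

    ``mean``/``sd`` are the reference-cohort moments fixed by
    :func:`standardize`; the standardized score is ``(raw - mean)/sd``.
    """

    sample_ids: list[str]
    raw: np.ndarray
    mean: float | None = None
    sd: float | None = None
    n_unmatched: int = 0

    @property
    def standardized(self) -> np.ndarray:
        if self.mean is None or self.sd is None:
            raise ValidationError("score has no stored standardization; call standardize()")
        return (self.raw - self.mean) / self.sd


def _imputed_centered(dosages: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean-impute missing calls, then center columns; returns (centered, norms)."""
    X = dosages.astype(float, copy=True)
    col_mean = np.nanmean(np.where(np.isnan(X), np.nan, X), axis=0)
    col_mean = np.nan_to_num(col_mean)  # all-missing columns -> 0
    nan_mask = np.isnan(X)
    if nan_mask.any():
        X[nan_mask] = np.take(col_mean, np.nonzero(nan_mask)[1])
    X -= X.mean(axis=0)
    norms = np.sqrt((X**2).sum(axis=0))
    return X, norms


def greedy_ld_prune(genotypes: GenotypeMatrix, params: PruneParams) -> np.ndarray:
    """Greedy left-to-right LD pruning; returns indices of kept variants.

    Variants must be sorted by ``(chrom, pos)``.  Sweeping in position
    order, a variant is kept only if its squared Pearson dosage
    correlation with every already-kept variant within ``window_kb`` on
    the same chromosome is at most ``r2_max``; when a pair violates the
    ceiling the earlier variant (already kept) wins.  Deterministic
    given the input order.
    """
    v = genotypes.variants
    key = list(zip(v["chrom"], v["pos"]))
    if any(a[0] == b[0] and a[1] > b[1] for a, b in zip(key, key[1:])):
        raise ValidationError("variants must be sorted by (chrom, pos)")
    X, norms = _imputed_centered(genotypes.dosages)
    window_bp = params.window_kb * 1000
    kept: list[int] = []
    pos = v["pos"].to_numpy()
    chrom = v["chrom"].to_numpy()
    kept_by_chrom: dict[str, list[int]] = {}
    for j in range(genotypes.n_variants):
        cands = kept_by_chrom.get(chrom[j], [])
        ok = True
        for k in reversed(cands):
            if pos[j] - pos[k] > window_bp:
                break
            if norms[j] == 0 or norms[k] == 0:
                continue  # monomorphic columns carry no LD
            r = float(X[:, j] @ X[:, k]) / (norms[j] * norms[k])
            if r * r > params.r2_max:
                ok = False
                break
        if ok:
            kept.append(j)
            kept_by_chrom.setdefault(chrom[j], []).append(j)
    return np.asarray(kept, dtype=int)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def threshold_variants(table: SumStats, mode: str, cutoff: float) -> SumStats:
    """Retain variants passing a p-value (``p_max``) or FDR (``fdr_max``) cutoff."""
    if not (0.0 < cutoff <= 1.0):
        raise ValidationError(f"cutoff must be in (0, 1], got {cutoff}")
    p = table.df["p"]
    if p.isna().any():
        raise ValidationError("thresholding requires p-values for every row")
    if mode == "p_max":
        keep = p <= cutoff
    elif mode == "fdr_max":
        keep = bh_fdr(p.to_numpy()) < cutoff
    else:
        raise ValidationError(f"unknown threshold mode {mode!r}")
    return SumStats(table.df.loc[keep].reset_index(drop=True), trait=table.trait)


def weights_from_sumstats(table: SumStats) -> GrsWeights:
    """Use a (pruned, thresholded) summary-stat table's betas as score weights."""
    df = table.df[["chrom", "pos", "id", "ea", "oa"]].copy()
    df["weight"] = table.df["beta"].astype(float)
    return GrsWeights(trait=table.trait, df=df.reset_index(drop=True))


def score_samples(genotypes: GenotypeMatrix, weights) -> ScoreVector:
    """Score samples: ``raw_i = sum_j dosage_ij * weight_j``.

    ``weights`` is a :class:`GrsWeights` or a weight DataFrame already
    harmonized to the panel's allele frame.  Missing dosages are
    replaced by the variant's panel mean; weight-table variants absent
    from the panel contribute zero and are counted in ``n_unmatched``.
    """
    wdf = weights.df if isinstance(weights, GrsWeights) else weights
    panel = genotypes.variants.reset_index(drop=True)
    if "chrom" in wdf.columns and "pos" in wdf.columns:
        keys = ["chrom", "pos", "ea", "oa"] if "oa" in wdf.columns else ["chrom", "pos", "ea"]
    else:
        keys = ["id", "ea"]
    panel_idx = panel.reset_index().set_index(keys)["index"]
    joined = wdf.set_index(keys)["weight"]
    common = joined.index.intersection(panel_idx.index)
    n_unmatched = len(wdf) - len(common)
    if len(common) == 0:
        raise EmptyOverlapError("no overlap between weight table and genotype panel")
    cols = panel_idx.loc[common].to_numpy()
    w = joined.loc[common].to_numpy(dtype=float)
    D = genotypes.dosages[:, cols].astype(float, copy=True)
    nan_mask = np.isnan(D)
    if nan_mask.any():
        col_mean = np.nan_to_num(np.nanmean(D, axis=0))
        D[nan_mask] = np.take(col_mean, np.nonzero(nan_mask)[1])
    raw = D @ w
    return ScoreVector(list(genotypes.sample_ids), raw, n_unmatched=n_unmatched)


def standardize(score: ScoreVector, reference_ids=None) -> ScoreVector:
    """Fix the standardization transform from a reference cohort.

    The mean and standard deviation (ddof=1) are computed over
    ``reference_ids`` (default: all samples) and stored; applying the
    stored transform to the reference subset then yields mean 0, sd 1.
    """
    if reference_ids is None:
        ref = score.raw
    else:
        idx = pd.Index(score.sample_ids).get_indexer(list(reference_ids))
        if np.any(idx < 0):
            raise ValidationError("reference_ids not all present in score")
        ref = score.raw[idx]
    if len(ref) < 2:
        raise DegenerateError("reference subset too small to standardize")
    mean = float(np.mean(ref))
    sd = float(np.std(ref, ddof=1))
    if sd == 0.0:
        raise DegenerateError("score is constant over the reference subset")
    return replace(score, mean=mean, sd=sd)


@dataclass
class CandidateEntry:
    """One point of the r²-threshold grid with its tuning-cohort fit."""

    r2_max: float
    weights: GrsWeights
    log_hr: float
    se: float


def select_candidate(grid: list[CandidateEntry]) -> CandidateEntry:
    """Pick the grid entry with the largest-magnitude hazard ratio.

    Ties go to the smaller r² threshold (the sparser score).
    """
    if not grid:
        raise ValidationError("candidate grid is empty")
    return min(grid, key=lambda e: (-abs(e.log_hr), e.r2_max))


def build_candidate_grid(
    table: SumStats,
    panel: GenotypeMatrix,
    tuning_records: pd.DataFrame,
    r2_grid=DEFAULT_R2_GRID,
    window_kb: int = 250,
    p_max: float = 1.0,
    stratify_by_sex: bool = True,
) -> list[CandidateEntry]:
    """Build one candidate GRS per r² threshold and fit each on a tuning cohort.

    ``tuning_records`` is a survival table (see ``metagrs.survival``)
    whose ``sample_id`` order matches the panel.  Each candidate's
    standardized score enters a Cox model alone; the fitted log-HR and
    SE are attached for :func:`select_candidate`.
    """
    from .survival import fit_cox  # deferred: survival does not depend on grs

    thresholded = threshold_variants(table, "p_max", p_max) if p_max < 1.0 else table
    grid: list[CandidateEntry] = []
    for r2 in sorted(r2_grid):
        kept = greedy_ld_prune(panel, PruneParams(window_kb=window_kb, r2_max=r2))
        kept_keys = panel.variants.iloc[kept][["chrom", "pos"]]
        merged = thresholded.df.merge(kept_keys, on=["chrom", "pos"], how="inner")
        if len(merged) == 0:
            continue
        weights = weights_from_sumstats(SumStats(merged, trait=table.trait))
        score = standardize(score_samples(panel, weights))
        rec = tuning_records.copy()
        rec["grs"] = score.standardized
        fit = fit_cox(rec, ["grs"], stratify_by_sex=stratify_by_sex)
        grid.append(
            CandidateEntry(r2_max=r2, weights=weights, log_hr=fit.beta["grs"], se=fit.robust_se["grs"])
        )
    if not grid:
        raise ValidationError("no candidate had any variants after pruning/thresholding")
    return grid


def component_correlation(scores: dict[str, ScoreVector], covariates: pd.DataFrame | None = None):
    """Pairwise partial correlations of standardized component scores.

    Each entry (a, b) is the average of the two linear-regression
    coefficients (a on b and b on a), adjusting both scores for the
    supplied covariates; q-values come from Benjamini–Hochberg over the
    K(K-1)/2 upper-triangle tests, and the leaf order from average-link
    hierarchical clustering of ``1 - |r|``.

    Returns ``(corr, qvalues, order)``: a K×K DataFrame, an
    upper-triangle long DataFrame with p/q-values, and the clustered
    label order.
    """
    labels = list(scores)
    K = len(labels)
    if K < 2:
        raise ValidationError("need at least two component scores")
    n = len(next(iter(scores.values())).raw)
    ids0 = next(iter(scores.values())).sample_ids
    S = np.empty((n, K))
    for k, lab in enumerate(labels):
        sv = scores[lab]
        if sv.sample_ids != ids0:
            raise ValidationError("all scores must cover the same samples in the same order")
        S[:, k] = sv.standardized
    if covariates is not None:
        C = np.column_stack([np.ones(n), np.asarray(covariates, dtype=float)])
        n_cov = C.shape[1] - 1
    else:
        C = np.ones((n, 1))
        n_cov = 0
    # residualize all scores on the covariates (Frisch–Waugh)
    R = S - C @ np.linalg.lstsq(C, S, rcond=None)[0]
    var = (R**2).mean(axis=0)
    if np.any(var == 0):
        raise DegenerateError("a component score is constant after covariate adjustment")
    cov = (R.T @ R) / n
    corr = np.empty((K, K))
    rows = []
    dof = n - 2 - n_cov
    for a in range(K):
        corr[a, a] = 1.0
        for b in range(a + 1, K):
            coef_ab = cov[a, b] / var[b]
            coef_ba = cov[a, b] / var[a]
            avg = 0.5 * (coef_ab + coef_ba)
            corr[a, b] = corr[b, a] = avg
            r_p = cov[a, b] / np.sqrt(var[a] * var[b])
            r_p = np.clip(r_p, -0.9999999999, 0.9999999999)
            tval = r_p * np.sqrt(dof / (1.0 - r_p**2))
            pval = 2.0 * t_dist.sf(abs(tval), dof)
            rows.append({"a": labels[a], "b": labels[b], "r": avg, "p": pval})
    tests = pd.DataFrame(rows)
    tests["q"] = bh_fdr(tests["p"].to_numpy())
    dist = 1.0 - np.abs(np.clip(corr, -1.0, 1.0))
    np.fill_diagonal(dist, 0.0)
    dist = 0.5 * (dist + dist.T)
    link = _hc_average(squareform(dist, checks=False))
    order = [labels[i] for i in leaves_list(link)]
    corr_df = pd.DataFrame(corr, index=labels, columns=labels)
    return corr_df, tests, order
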