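"""Stack standardized component GRSs into a meta-score.

The per-component combination weights (log-odds gamma_k) come from an
elastic-net logistic regression of case status on the K standardized
component scores, with unpenalized covariates, selected over a penalty
grid by cross-validated AUC.  The fitted stack is then collapsed to a
single per-SNP weight table,

    w_j = sum_k (gamma_k / sigma_k) * alpha_jk,

where sigma_k is the component's reference-cohort standard deviation
and alpha_jk its per-allele weight for SNP j (zero when the SNP is not
in component k).  Scoring a cohort with the collapsed table reproduces
the gamma-weighted sum of standardized component scores up to one
additive constant (the dropped standardization means), so the collapsed
table is an exact stand-alone representation of the stack.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.metrics import roc_auc_score

from .errors import HarmonizationError, ValidationError
from .grs import GrsWeights, ScoreVector
from .sumstats import QcFilterSpec

__all__ = [
    "StackConfig",
    "MetaModel",
    "fit_stack_cv",
    "collapse_weights",
    "sensitivity_qc_refit",
]


@dataclass(frozen=True)
class StackConfig:
    """Cross-validation and penalty-grid settings for the stack fit.

    ``penalty_grid`` is a list of ``(mixing, strength)`` pairs; when
    empty, a default grid of mixings {0.1, 0.5, 0.9} by ``n_strengths``
    log-spaced strengths (auto-scaled from the data) is used.
    """

    n_folds: int = 10
    penalty_grid: tuple = ()
    mixing_grid: tuple = (0.1, 0.5, 0.9)
    n_strengths: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValidationError("n_folds must be >= 2")
        for mix, strength in self.penalty_grid:
            if strength <= 0:
                raise ValidationError("penalty strengths must be positive")
            if not (0.0 <= mix <= 1.0):
                raise ValidationError("mixing must lie in [0, 1]")


@dataclass
class MetaModel:
    """The fitted stack: per-component log-odds and stored standardizations."""

    labels: list[str]
    gamma: pd.Series
    sigma: pd.Series
    covariate_coefs: pd.Series
    intercept: float
    chosen_penalty: tuple
    cv_auc_trace: pd.DataFrame

    def to_text(self, path) -> None:
        """Serialize to a structured text file."""
        with open(path, "w") as fh:
            fh.write(f"# metagrs MetaModel\nintercept\t{float(self.intercept)!r}\n")
            fh.write(f"penalty_mixing\t{float(self.chosen_penalty[0])!r}\n")
            fh.write(f"penalty_strength\t{float(self.chosen_penalty[1])!r}\n")
            for lab in self.labels:
                fh.write(
                    f"component\t{lab}\t{float(self.gamma[lab])!r}\t{float(self.sigma[lab])!r}\n"
                )
            for name, v in self.covariate_coefs.items():
                fh.write(f"covariate\t{name}\t{float(v)!r}\n")


def _fold_assignment(sample_ids, outcome, n_folds, seed) -> np.ndarray:
    """Stratified fold labels that depend on sample identity, not row order."""
    ids = np.asarray(sample_ids)
    y = np.asarray(outcome).astype(int)
    order = np.argsort(ids, kind="stable")
    rng = np.random.default_rng(seed)
    folds = np.empty(len(ids), dtype=int)
    for cls in np.unique(y):
        cls_rows = order[y[order] == cls]
        perm = rng.permutation(len(cls_rows))
        folds[cls_rows[perm]] = np.arange(len(cls_rows)) % n_folds
    return folds


def _fit_enet(X, y, alpha_vec, mixing):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit_regularized(
            method="elastic_net", alpha=alpha_vec, L1_wt=mixing, maxiter=200
        )
    return np.asarray(res.params)


def fit_stack_cv(
    components: dict[str, ScoreVector],
    outcome,
    covariates: pd.DataFrame | None = None,
    config: StackConfig = StackConfig(),
) -> MetaModel:
    """Fit the elastic-net stack with cross-validated penalty selection.

    ``components`` maps labels to standardized scores over the same
    samples; ``outcome`` is the binary case flag.  Component
    coefficients are penalized, covariates and intercept are not.  For
    each grid point the held-out predictions over the seed-derived
    stratified folds are pooled into one AUC; the maximizing penalty is
    refit on the full data.
    """
    labels = list(components)
    K = len(labels)
    first = components[labels[0]]
    n = len(first.raw)
    y = np.asarray(outcome, dtype=float)
    if len(y) != n:
        raise ValidationError("outcome length mismatch")
    if len(np.unique(y)) < 2:
        raise ValidationError("outcome must contain both classes")
    if n < config.n_folds:
        raise ValidationError("fewer samples than folds")
    Z = np.empty((n, K))
    sigma = {}
    for k, lab in enumerate(labels):
        sv = components[lab]
        if sv.sample_ids != first.sample_ids:
            raise ValidationError("components must cover the same samples in the same order")
        Z[:, k] = sv.standardized
        sigma[lab] = sv.sd
    if covariates is not None:
        cov_names = list(covariates.columns)
        C = covariates.to_numpy(dtype=float)
        X = np.column_stack([np.ones(n), Z, C])
    else:
        cov_names = []
        X = np.column_stack([np.ones(n), Z])

    grid = list(config.penalty_grid)
    if not grid:
        # lasso-style maximal strength from the score-outcome covariance
        s_max = float(np.abs(Z.T @ (y - y.mean())).max() / n)
        s_max = max(s_max, 1e-6)
        strengths = np.geomspace(s_max, s_max * 1e-3, config.n_strengths)
        grid = [(mix, s) for mix in config.mixing_grid for s in strengths]

    folds = _fold_assignment(first.sample_ids, y, config.n_folds, config.seed)
    trace = []
    best = None
    for mix, strength in grid:
        alpha_vec = np.concatenate([[0.0], np.full(K, strength), np.zeros(len(cov_names))])
        pred = np.empty(n)
        for f in range(config.n_folds):
            test = folds == f
            params = _fit_enet(X[~test], y[~test], alpha_vec, mix)
            lin = X[test] @ params
            pred[test] = 1.0 / (1.0 + np.exp(-lin))
        auc = float(roc_auc_score(y, pred))
        trace.append({"mixing": mix, "strength": strength, "cv_auc": auc})
        if best is None or auc > best[0]:
            best = (auc, mix, strength, pred.copy())
    _, mix, strength, _ = best
    alpha_vec = np.concatenate([[0.0], np.full(K, strength), np.zeros(len(cov_names))])
    params = _fit_enet(X, y, alpha_vec, mix)
    gamma = pd.Series(params[1 : 1 + K], index=labels)
    cov_coefs = pd.Series(params[1 + K :], index=cov_names)
    return MetaModel(
        labels=labels,
        gamma=gamma,
        sigma=pd.Series(sigma),
        covariate_coefs=cov_coefs,
        intercept=float(params[0]),
        chosen_penalty=(mix, strength),
        cv_auc_trace=pd.DataFrame(trace),
    )


VARIANT_KEY = ["chrom", "pos"]


def collapse_weights(model: MetaModel, components: dict[str, GrsWeights]) -> pd.DataFrame:
    """Collapse the stack to per-SNP weights over the union of component variants.

    Components must share one allele frame: a variant appearing in two
    components with different effect/other alleles raises
    :class:`HarmonizationError`.  Variants whose collapsed weight is
    exactly zero are dropped.
    """
    if set(model.labels) != set(components):
        raise ValidationError("component labels do not match the fitted model")
    pieces = []
    for lab in model.labels:
        comp = components[lab]
        scale = model.gamma[lab] / model.sigma[lab]
        part = comp.df[["chrom", "pos", "id", "ea", "oa"]].copy()
        part["contrib"] = comp.df["weight"].to_numpy(dtype=float) * scale
        pieces.append(part)
    allv = pd.concat(pieces, ignore_index=True)
    frames = allv.groupby(VARIANT_KEY)[["ea", "oa"]].nunique()
    if (frames > 1).any(axis=None):
        bad = frames[(frames > 1).any(axis=1)].index.tolist()
        raise HarmonizationError(f"conflicting allele frames at {bad[:5]}")
    out = (
        allv.groupby(VARIANT_KEY + ["ea", "oa"], as_index=False)
        .agg(id=("id", "first"), weight=("contrib", "sum"))
        .sort_values(VARIANT_KEY, kind="stable")
        .reset_index(drop=True)
    )
    out = out.loc[out["weight"] != 0.0].reset_index(drop=True)
    return out[["chrom", "pos", "id", "ea", "oa", "weight"]]


def sensitivity_qc_refit(
    model: MetaModel,
    components: dict[str, GrsWeights],
    spec: QcFilterSpec,
    annotations: pd.DataFrame,
    genotypes=None,
    records: pd.DataFrame | None = None,
    stratify_by_sex: bool = True,
) -> tuple[pd.DataFrame, dict]:
    """Collapse after per-variant QC filtering and report the association delta.

    ``annotations`` carries per-variant ``chrom, pos, eaf`` (and
    ``info`` when ``spec.info_min > 0``).  When a genotype panel and
    survival records are supplied, the HR per SD of the collapsed score
    before vs after filtering is reported.
    """
    ann = annotations.set_index(VARIANT_KEY)
    keep_idx = pd.Series(True, index=ann.index)
    if spec.maf_min > 0:
        maf = np.minimum(ann["eaf"], 1.0 - ann["eaf"])
        keep_idx &= maf >= spec.maf_min
    if spec.info_min > 0:
        if "info" not in ann.columns:
            raise ValidationError("INFO filtering requires an info annotation column")
        keep_idx &= ann["info"] >= spec.info_min
    filtered = {}
    for lab, comp in components.items():
        key = pd.MultiIndex.from_frame(comp.df[VARIANT_KEY])
        known = key.isin(keep_idx.index)
        keep = np.zeros(len(comp.df), dtype=bool)
        keep[known] = keep_idx.reindex(key[known]).to_numpy()
        filtered[lab] = GrsWeights(comp.trait, comp.df.loc[keep].reset_index(drop=True))
    table_before = collapse_weights(model, components)
    table_after = collapse_weights(model, filtered)
    report: dict = {"n_before": len(table_before), "n_after": len(table_after)}
    if genotypes is not None and records is not None:
        from .grs import score_samples, standardize
        from .survival import fit_cox, hr_per_sd

        for tag, table in (("before", table_before), ("after", table_after)):
            score = standardize(score_samples(genotypes, table))
            rec = records.copy()
            rec["meta"] = score.standardized
            fit = fit_cox(rec, ["meta"], stratify_by_sex=stratify_by_sex)
            report[f"hr_{tag}"], _ = hr_per_sd(fit, "meta")
        report["hr_delta"] = report["hr_after"] - report["hr_before"]
    return table_after, report
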