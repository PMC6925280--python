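"""Survival-analysis machinery for evaluating risk scores.

The central model is a Cox proportional-hazards regression on the age
time scale: attained age is the time axis, so every participant enters
the risk set at their assessment age (delayed entry / left truncation)
and exits at event or censoring age, administratively capped.  Fits are
sex-stratified, weighted by inverse selection probability when a
designed oversampling produced the cohort, and reported with sandwich
(robust) standard errors.

On top of the fit sit the usual evaluation tools: hazard ratio per
standard deviation, hazard ratios for extreme percentile bins against a
middle reference bin, Harrell's concordance under left truncation,
Kaplan–Meier curves with a delayed-entry log-rank test, predicted
cumulative incidence ``1 - exp(-H0(t) * exp(x'beta))`` with delta-method
intervals, decile calibration with a baseline-rate rescaling, and the
threshold-model conversion of observed-scale R² to the liability scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from scipy import stats

from .errors import DegenerateError, ValidationError

__all__ = [
    "CoxResult",
    "PercentileBinSpec",
    "LiabilityParams",
    "fit_cox",
    "hr_per_sd",
    "percentile_bin_hr",
    "harrell_c",
    "kaplan_meier",
    "cumulative_incidence",
    "calibration_by_decile",
    "r2_to_liability",
    "explained_heritability",
    "test_interaction",
]

REQUIRED_COLUMNS = ("entry_age", "exit_age", "event")


@dataclass
class CoxResult:
    """A fitted left-truncated Cox model.

    ``baseline_cumhaz`` maps each stratum to a DataFrame with columns
    ``time, cumhaz, var`` — the Breslow cumulative hazard evaluated at
    the weighted covariate mean ``norm_mean`` (covariates are centred
    before the baseline pass, as in standard survival software).
    """

    beta: pd.Series
    robust_se: pd.Series
    covariance: pd.DataFrame
    baseline_cumhaz: dict
    norm_mean: pd.Series
    schoenfeld_p: float
    loglik: float
    predictors: list[str]
    strata_col: str | None = None


def _validate_records(records: pd.DataFrame, predictors) -> None:
    for c in REQUIRED_COLUMNS:
        if c not in records.columns:
            raise ValidationError(f"survival records missing column {c!r}")
    for c in predictors:
        if c not in records.columns:
            raise ValidationError(f"predictor column {c!r} not in records")
    if (records["exit_age"] <= records["entry_age"]).any():
        raise ValidationError("exit_age must exceed entry_age for every record")
    if records["event"].sum() == 0:
        raise DegenerateError("no events in the survival records")


def _risk_set_sums(entry, exit_, values, times):
    """Sum ``values`` over delayed-entry risk sets {entry < t <= exit} at each t.

    Uses sorted prefix sums so the whole event-time grid costs
    O(n log n) instead of O(n) per time point.  ``values`` is (n,) or
    (n, q); returns an array of shape (len(times),) or (len(times), q).
    """
    v = np.atleast_2d(values.T).T  # (n, q)
    e_ord = np.argsort(exit_, kind="stable")
    ex_sorted = exit_[e_ord]
    pe = np.vstack([np.zeros(v.shape[1]), np.cumsum(v[e_ord], axis=0)])
    n_ord = np.argsort(entry, kind="stable")
    en_sorted = entry[n_ord]
    pn = np.vstack([np.zeros(v.shape[1]), np.cumsum(v[n_ord], axis=0)])
    k_exit = np.searchsorted(ex_sorted, times, side="left")  # exits strictly before t
    k_entry = np.searchsorted(en_sorted, times, side="left")  # entries strictly before t
    out = pn[k_entry] - pe[k_exit]
    return out if np.ndim(values) > 1 else out[:, 0]


def _event_sums_at(exit_, ev, values, times):
    """Sum ``values`` over events at each exact time in ``times``."""
    v = np.atleast_2d(values.T).T
    ev_times = exit_[ev]
    order = np.argsort(ev_times, kind="stable")
    sorted_t = ev_times[order]
    pv = np.vstack([np.zeros(v.shape[1]), np.cumsum(v[ev][order], axis=0)])
    lo = np.searchsorted(sorted_t, times, side="left")
    hi = np.searchsorted(sorted_t, times, side="right")
    out = pv[hi] - pv[lo]
    return out if np.ndim(values) > 1 else out[:, 0]


def _schoenfeld_global_p(df, X, beta_vec, eta, strata_col, covariance) -> float:
    """Grambsch–Therneau global test with the identity time transform.

    Schoenfeld residuals are computed against risk sets with delayed
    entry (which standard library residuals do not support); the global
    chi-square is ``d (sum z_i s_i)' V (sum z_i s_i) / sum z_i^2`` with
    ``z`` the demeaned event times and ``V`` the covariance of beta.
    """
    u_rows, times_all = [], []
    groups = df.groupby(strata_col, observed=True) if strata_col else [("__all__", df)]
    for _, g in groups:
        idx = g.index.to_numpy()
        entry = g["entry_age"].to_numpy()
        exit_ = g["exit_age"].to_numpy()
        ev = g["event"].to_numpy().astype(bool)
        if not ev.any():
            continue
        w = g["__w"].to_numpy()
        rw = w * np.exp(eta[idx])
        Xg = X[idx]
        times = np.unique(exit_[ev])
        denom = _risk_set_sums(entry, exit_, rw, times)
        xbar = _risk_set_sums(entry, exit_, rw[:, None] * Xg, times) / denom[:, None]
        # per event time: sum_i w_i (x_i - xbar(t)), replicated per event
        wx_ev = _event_sums_at(exit_, ev, w[:, None] * Xg, times)
        w_ev = _event_sums_at(exit_, ev, w, times)
        d_ev = _event_sums_at(exit_, ev, np.ones_like(w), times).astype(int)
        u_rows.append((wx_ev - w_ev[:, None] * xbar, times, d_ev))
        times_all.extend(np.repeat(times, d_ev))
    if not u_rows:
        return float("nan")
    d = len(times_all)
    zbar = float(np.mean(times_all))
    z2 = float(np.sum((np.asarray(times_all) - zbar) ** 2))
    if d < 2 or z2 == 0:
        return float("nan")
    u = np.zeros(X.shape[1])
    for s_rows, times, d_ev in u_rows:
        # events at the same time share the risk-set mean, so weight by (t - zbar)
        u += ((times - zbar)[:, None] * s_rows).sum(axis=0)
    V = covariance.to_numpy()
    stat = float(d * u @ V @ u / z2)
    return float(stats.chi2.sf(stat, X.shape[1]))


def _breslow_baseline(df, eta, strata_col):
    """Weighted Breslow cumulative hazard per stratum, with a Poisson-type variance."""
    out = {}
    groups = df.groupby(strata_col, observed=True) if strata_col else [("__all__", df)]
    for name, g in groups:
        entry = g["entry_age"].to_numpy()
        exit_ = g["exit_age"].to_numpy()
        ev = g["event"].to_numpy().astype(bool)
        w = g["__w"].to_numpy()
        risk = w * np.exp(eta[g.index.to_numpy()])
        times = np.unique(exit_[ev])
        denom = _risk_set_sums(entry, exit_, risk, times)
        dw = _event_sums_at(exit_, ev, w, times)
        dw2 = _event_sums_at(exit_, ev, w**2, times)
        out[name] = pd.DataFrame(
            {
                "time": times,
                "cumhaz": np.cumsum(dw / denom),
                "var": np.cumsum(dw2 / denom**2),
            }
        )
    return out


def fit_cox(
    records: pd.DataFrame,
    predictor_names,
    stratify_by_sex: bool = True,
    weight_col: str = "weight",
) -> CoxResult:
    """Fit a sex-stratified, IPW-weighted Cox model with delayed entry.

    ``records`` needs ``entry_age, exit_age, event`` plus the predictor
    columns; ``sex`` when stratifying and ``weight`` when weighting
    (absent weights default to 1).  Standard errors are the sandwich
    estimator grouped by individual; ties use lifelines' Efron-style
    partial likelihood; the baseline cumulative hazard is Breslow's
    estimator at the weighted covariate mean.
    """
    predictors = list(predictor_names)
    _validate_records(records, predictors)
    strata_col = "sex" if stratify_by_sex else None
    if strata_col and strata_col not in records.columns:
        raise ValidationError("stratified fit requires a 'sex' column")
    cols = list(REQUIRED_COLUMNS) + predictors
    if strata_col:
        cols.append(strata_col)
    df = records[cols].reset_index(drop=True).copy()
    df["__w"] = (
        records[weight_col].to_numpy(dtype=float) if weight_col in records.columns else 1.0
    )
    if (df["__w"] <= 0).any():
        raise ValidationError("weights must be positive")
    for p in predictors:
        grouped = df.groupby(strata_col, observed=True)[p] if strata_col else [(0, df[p])]
        if all(g.nunique() <= 1 for _, g in grouped):
            raise ValidationError(f"predictor {p!r} is constant within all strata")

    cph = CoxPHFitter(penalizer=0.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(
            df,
            duration_col="exit_age",
            event_col="event",
            entry_col="entry_age",
            weights_col="__w",
            strata=[strata_col] if strata_col else None,
            robust=True,
        )
    beta = cph.params_.copy()
    beta.index = [i if isinstance(i, str) else i[-1] for i in beta.index]
    se = pd.Series(np.sqrt(np.diag(cph.variance_matrix_.to_numpy())), index=beta.index)
    covariance = pd.DataFrame(
        cph.variance_matrix_.to_numpy(), index=beta.index, columns=beta.index
    )

    w = df["__w"].to_numpy()
    X = df[predictors].to_numpy(dtype=float)
    norm_mean = pd.Series((X * w[:, None]).sum(axis=0) / w.sum(), index=predictors)
    eta = (X - norm_mean.to_numpy()) @ beta[predictors].to_numpy()
    baseline = _breslow_baseline(df, eta, strata_col)

    schoenfeld_p = _schoenfeld_global_p(
        df, X, beta[predictors].to_numpy(), eta, strata_col, covariance
    )

    return CoxResult(
        beta=beta,
        robust_se=se,
        covariance=covariance,
        baseline_cumhaz=baseline,
        norm_mean=norm_mean,
        schoenfeld_p=schoenfeld_p,
        loglik=float(cph.log_likelihood_),
        predictors=predictors,
        strata_col=strata_col,
    )


def hr_per_sd(result: CoxResult, predictor: str) -> tuple[float, tuple[float, float]]:
    """Hazard ratio and 95% CI for a predictor entered in SD units."""
    b = float(result.beta[predictor])
    s = float(result.robust_se[predictor])
    return float(np.exp(b)), (float(np.exp(b - 1.96 * s)), float(np.exp(b + 1.96 * s)))


@dataclass(frozen=True)
class PercentileBinSpec:
    """Cumulative-percentile bin edges and the reference bin index."""

    edges: tuple = (0.0, 0.10, 0.45, 0.55, 0.90, 1.0)
    reference: int = 2  # the 45-55% middle bin of the default edges

    def __post_init__(self) -> None:
        e = np.asarray(self.edges, dtype=float)
        if e[0] != 0.0 or e[-1] != 1.0 or np.any(np.diff(e) <= 0):
            raise ValidationError("edges must increase strictly from 0 to 1")
        if not (0 <= self.reference < len(e) - 1):
            raise ValidationError("reference bin index out of range")


def percentile_bin_hr(
    scores: np.ndarray,
    records: pd.DataFrame,
    spec: PercentileBinSpec = PercentileBinSpec(),
    stratify_by_sex: bool = True,
) -> pd.DataFrame:
    """Hazard ratios of score percentile bins against a reference bin.

    Bin membership (by empirical score quantiles) enters a single Cox
    fit as a categorical predictor with the reference bin (by default
    the middle 45–55%) omitted.  Returns one row per bin with HR and CI
    (the reference bin has HR 1 by construction).
    """
    scores = np.asarray(scores, dtype=float)
    if len(scores) != len(records):
        raise ValidationError("scores and records length mismatch")
    qs = np.quantile(scores, spec.edges)
    qs[0], qs[-1] = -np.inf, np.inf
    bins = np.digitize(scores, qs[1:-1], right=True)
    n_bins = len(spec.edges) - 1
    counts = np.bincount(bins, minlength=n_bins)
    if np.any(counts == 0):
        raise ValidationError(f"empty percentile bin(s): {np.nonzero(counts == 0)[0].tolist()}")
    df = records.copy().reset_index(drop=True)
    dummy_cols = []
    for b in range(n_bins):
        if b == spec.reference:
            continue
        col = f"bin_{b}"
        df[col] = (bins == b).astype(float)
        dummy_cols.append(col)
    fit = fit_cox(df, dummy_cols, stratify_by_sex=stratify_by_sex)
    rows = []
    for b in range(n_bins):
        lo_pct, hi_pct = spec.edges[b], spec.edges[b + 1]
        if b == spec.reference:
            rows.append({"bin": b, "lo_pct": lo_pct, "hi_pct": hi_pct, "hr": 1.0,
                         "ci_low": 1.0, "ci_high": 1.0, "n": int(counts[b])})
        else:
            hr, (lo, hi) = hr_per_sd(fit, f"bin_{b}")
            rows.append({"bin": b, "lo_pct": lo_pct, "hi_pct": hi_pct, "hr": hr,
                         "ci_low": lo, "ci_high": hi, "n": int(counts[b])})
    return pd.DataFrame(rows)


def harrell_c(records: pd.DataFrame, risk_score) -> tuple[float, tuple[float, float]]:
    """Harrell's C under left truncation.

    A pair is comparable when one member's event age falls strictly
    inside the other's at-risk window ``(entry, exit)`` (or at a
    censored exit); the pair is concordant when the member failing
    first carries the higher risk score, with score ties counting 0.5.
    The CI uses the between-event variability of per-event concordance
    fractions — a leave-one-event-out (jackknife-style) approximation.
    """
    score = np.asarray(risk_score, dtype=float)
    entry = records["entry_age"].to_numpy(dtype=float)
    exit_ = records["exit_age"].to_numpy(dtype=float)
    ev = records["event"].to_numpy().astype(bool)
    if len(score) != len(records):
        raise ValidationError("risk_score and records length mismatch")
    conc = 0.0
    n_pairs = 0
    per_event = []
    for i in np.nonzero(ev)[0]:
        t = exit_[i]
        later = (entry < t) & ((exit_ > t) | ((exit_ == t) & ~ev))
        later[i] = False
        m = int(later.sum())
        if m == 0:
            continue
        c_i = float(np.sum(score[i] > score[later]) + 0.5 * np.sum(score[i] == score[later]))
        conc += c_i
        n_pairs += m
        per_event.append(c_i / m)
    if n_pairs == 0:
        raise ValidationError("no comparable pairs under left truncation")
    c = conc / n_pairs
    if len(per_event) > 1:
        se = float(np.std(per_event, ddof=1) / np.sqrt(len(per_event)))
    else:
        se = float("nan")
    lo, hi = max(0.0, c - 1.96 * se), min(1.0, c + 1.96 * se)
    return float(c), (lo, hi)


def kaplan_meier(records: pd.DataFrame, groups) -> tuple[dict, float]:
    """Product-limit curves per group with a delayed-entry log-rank test.

    ``groups`` is a per-record label array.  Returns a mapping
    ``label -> survival-curve DataFrame (time, survival)`` and the
    log-rank p-value across groups, both accounting for left
    truncation.
    """
    groups = np.asarray(groups)
    if len(groups) != len(records):
        raise ValidationError("group labels must cover every record")
    labels = pd.unique(groups)
    if len(labels) == 0:
        raise ValidationError("empty group")
    entry = records["entry_age"].to_numpy(dtype=float)
    exit_ = records["exit_age"].to_numpy(dtype=float)
    ev = records["event"].to_numpy().astype(bool)
    curves = {}
    for lab in labels:
        m = groups == lab
        kmf = KaplanMeierFitter()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            kmf.fit(exit_[m], ev[m], entry=entry[m])
        sf = kmf.survival_function_
        curves[lab] = pd.DataFrame({"time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy()})
    p = _logrank_delayed_entry(entry, exit_, ev, groups, labels)
    return curves, p


def _logrank_delayed_entry(entry, exit_, ev, groups, labels) -> float:
    G = len(labels)
    if G < 2:
        return float("nan")
    times = np.unique(exit_[ev])
    ones = np.ones(len(entry))
    member = np.column_stack([(groups == lab).astype(float) for lab in labels])
    n_g_t = _risk_set_sums(entry, exit_, member, times)  # (T, G)
    N_t = _risk_set_sums(entry, exit_, ones, times)
    d_g_t = _event_sums_at(exit_, ev, member, times)
    D_t = _event_sums_at(exit_, ev, ones, times)
    ok = (N_t > 1) & (D_t > 0)
    n_g_t, N_t, d_g_t, D_t = n_g_t[ok], N_t[ok], d_g_t[ok], D_t[ok]
    O = d_g_t.sum(axis=0)
    frac = n_g_t / N_t[:, None]
    E = (D_t[:, None] * frac).sum(axis=0)
    hyper = D_t * (N_t - D_t) / (N_t - 1)
    V = np.einsum("t,tg->g", hyper, frac * (1 - frac)) * np.eye(G)
    V -= np.einsum("t,tg,th->gh", hyper, frac, frac) * (1 - np.eye(G))
    d = (O - E)[: G - 1]
    Vsub = V[: G - 1, : G - 1]
    try:
        stat = float(d @ np.linalg.solve(Vsub, d))
    except np.linalg.LinAlgError:
        stat = float(d @ np.linalg.pinv(Vsub) @ d)
    return float(stats.chi2.sf(stat, G - 1))


def cumulative_incidence(
    result: CoxResult, covariate_profile: dict, t_grid
) -> pd.DataFrame:
    """Predicted cumulative incidence ``1 - exp(-H0(t) exp(x'beta))`` per stratum.

    ``covariate_profile`` gives the predictor values of interest
    (centred internally at the training mean, matching the baseline).
    The 95% CI propagates the baseline-hazard variance and the robust
    covariance of beta on the log-cumulative-hazard scale.  Times past
    the last event are flat (a warning is issued).
    """
    missing = [p for p in result.predictors if p not in covariate_profile]
    if missing:
        raise ValidationError(f"profile missing predictors: {missing}")
    x = np.array([covariate_profile[p] for p in result.predictors], dtype=float)
    xc = x - result.norm_mean[result.predictors].to_numpy()
    b = result.beta[result.predictors].to_numpy()
    eta = float(xc @ b)
    var_eta = float(
        xc @ result.covariance.loc[result.predictors, result.predictors].to_numpy() @ xc
    )
    t_grid = np.asarray(t_grid, dtype=float)
    rows = []
    for stratum, bh in result.baseline_cumhaz.items():
        tmax = bh["time"].iloc[-1] if len(bh) else -np.inf
        if np.any(t_grid > tmax):
            warnings.warn(
                f"stratum {stratum}: extrapolating beyond last event age {tmax}; curve is flat",
                stacklevel=2,
            )
        idx = np.searchsorted(bh["time"].to_numpy(), t_grid, side="right") - 1
        H0 = np.where(idx >= 0, bh["cumhaz"].to_numpy()[np.maximum(idx, 0)], 0.0)
        vH0 = np.where(idx >= 0, bh["var"].to_numpy()[np.maximum(idx, 0)], 0.0)
        H = H0 * np.exp(eta)
        with np.errstate(divide="ignore", invalid="ignore"):
            se_logH = np.sqrt(np.where(H0 > 0, vH0 / H0**2, 0.0) + var_eta)
        lo = 1.0 - np.exp(-H * np.exp(-1.96 * se_logH))
        hi = 1.0 - np.exp(-H * np.exp(1.96 * se_logH))
        risk = 1.0 - np.exp(-H)
        for t, r, l, h in zip(t_grid, risk, lo, hi):
            rows.append({"stratum": stratum, "time": t, "risk": r, "ci_low": l, "ci_high": h})
    return pd.DataFrame(rows)


def calibration_by_decile(
    predicted_risk, observed, rate_ratio: float = 1.0
) -> pd.DataFrame:
    """Observed event proportions within deciles of rescaled predicted risk.

    Predictions from an event-enriched derivation model are rescaled to
    the target cohort's baseline rate on the odds scale (odds divided by
    ``rate_ratio``), then cut into deciles; per-decile observed
    proportions carry exact binomial 95% intervals.
    """
    if rate_ratio <= 0:
        raise ValidationError("rate_ratio must be positive")
    p = np.asarray(predicted_risk, dtype=float)
    y = np.asarray(observed, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValidationError("predicted risks must lie strictly in (0, 1)")
    p_adj = p / (p + rate_ratio * (1.0 - p))
    try:
        dec = np.asarray(pd.qcut(p_adj, 10, labels=False, duplicates="drop"), dtype=float)
    except ValueError:
        dec = np.zeros(len(p_adj))
    # all-identical predictions leave no usable quantile edges -> one bin
    dec = np.nan_to_num(dec, nan=0.0).astype(int)
    rows = []
    for d in np.unique(dec):
        m = dec == d
        n, k = int(m.sum()), int(y[m].sum())
        ci = stats.binomtest(k, n).proportion_ci(confidence_level=0.95, method="exact")
        rows.append(
            {
                "decile": int(d),
                "n": n,
                "events": k,
                "mean_predicted": float(p_adj[m].mean()),
                "observed": k / n,
                "ci_low": float(ci.low),
                "ci_high": float(ci.high),
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class LiabilityParams:
    """Threshold-model parameters: population prevalence K, sample case fraction P."""

    K: float
    P: float
    h2_grid: tuple = (0.1, 0.2, 0.3, 0.4)

    def __post_init__(self) -> None:
        if not (0.0 < self.K < 1.0) or not (0.0 < self.P < 1.0):
            raise ValidationError("K and P must lie strictly in (0, 1)")


def liability_factor(K: float, P: float) -> float:
    """Multiplier taking observed-scale R² to the liability scale.

    With threshold ``t = Phi^-1(1-K)`` and ``z = phi(t)``, the linear
    transformation factor is ``K^2 (1-K)^2 / (z^2 P (1-P))``; at
    ``P = K`` it reduces to the classic ``K(1-K)/z^2``.
    """
    t = stats.norm.ppf(1.0 - K)
    z = stats.norm.pdf(t)
    return (K * (1.0 - K)) ** 2 / (z**2 * P * (1.0 - P))


def r2_to_liability(
    r2_observed: float, params: LiabilityParams, method: str = "linear"
) -> float:
    """Convert an observed-scale R² for a binary trait to the liability scale.

    ``method="linear"`` applies the constant factor of
    :func:`liability_factor`; ``method="ascertained"`` applies the
    nonlinear correction for case-control ascertainment
    ``C·R2 / (1 + C·theta·R2)`` with ``theta`` the ascertainment term of
    the threshold model.
    """
    if not (0.0 <= r2_observed < 1.0):
        raise ValidationError("r2_observed must lie in [0, 1)")
    K, P = params.K, params.P
    C = liability_factor(K, P)
    if method == "linear":
        return C * r2_observed
    if method == "ascertained":
        t = stats.norm.ppf(1.0 - K)
        z = stats.norm.pdf(t)
        m = z / K  # mean liability of cases
        theta = m * (P - K) / (1.0 - K) * (m * (P - K) / (1.0 - K) - t)
        return C * r2_observed / (1.0 + C * theta * r2_observed)
    raise ValidationError(f"unknown method {method!r}")


def explained_heritability(r2_liability: float, h2_grid) -> pd.Series:
    """Fraction of trait heritability captured: ``r2_liability / h2`` per grid value."""
    h2 = np.asarray(h2_grid, dtype=float)
    if np.any((h2 <= 0) | (h2 >= 1)):
        raise ValidationError("h2 values must lie strictly in (0, 1)")
    return pd.Series(r2_liability / h2, index=h2)


def test_interaction(
    records: pd.DataFrame,
    predictor_a: str,
    predictor_b: str,
    model: str = "cox",
    stratify_by_sex: bool = True,
) -> float:
    """Wald p-value for the product term ``a x b`` added to the model.

    ``model="cox"`` adds the interaction to the left-truncated Cox fit;
    ``model="logistic"`` uses a logistic regression of the event flag
    (the convention for medication-interaction checks).
    """
    a = records[predictor_a].to_numpy(dtype=float)
    bvals = records[predictor_b].to_numpy(dtype=float)
    if np.ptp(bvals) == 0 or np.ptp(a) == 0:
        raise ValidationError("interaction requires non-constant predictors")
    df = records.copy().reset_index(drop=True)
    inter = f"{predictor_a}_x_{predictor_b}"
    df[inter] = a * bvals
    design = [predictor_a, predictor_b, inter]
    X = df[design].to_numpy()
    if np.linalg.matrix_rank(X - X.mean(axis=0)) < 3:
        raise ValidationError("product term is collinear with the main effects")
    if model == "cox":
        strat = stratify_by_sex and predictor_b != "sex"
        fit = fit_cox(df, design, stratify_by_sex=strat)
        wald = float(fit.beta[inter] / fit.robust_se[inter])
        return float(2.0 * stats.norm.sf(abs(wald)))
    if model == "logistic":
        import statsmodels.api as sm

        Xd = sm.add_constant(df[design].to_numpy())
        res = sm.GLM(df["event"].to_numpy(), Xd, family=sm.families.Binomial()).fit()
        wald = float(res.params[-1] / res.bse[-1])
        return float(2.0 * stats.norm.sf(abs(wald)))
    raise ValidationError(f"unknown model {model!r}")
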