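"""Left-truncated Cox machinery, concordance, KM, calibration, liability scale."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from metagrs import (
    DegenerateError,
    ValidationError,
    calibration_by_decile,
    cumulative_incidence,
    explained_heritability,
    fit_cox,
    harrell_c,
    hr_per_sd,
    kaplan_meier,
    percentile_bin_hr,
    r2_to_liability,
)
from metagrs import test_interaction as interaction_wald_p
from metagrs.survival import CoxResult, LiabilityParams, PercentileBinSpec, liability_factor
from metagrs.simulate import simulate_survival

from conftest import harrell_c_oracle


def _cohort(seed, n, log_hr=0.0, followup=None):
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    rec = simulate_survival(log_hr * x, rng, followup_years=followup)
    rec["x"] = x
    return rec.loc[rec["prevalent"] == 0].reset_index(drop=True)


class TestFitCox:
    def test_null_predictor_recovers_zero(self):
        inc = _cohort(1, 10_000)
        fit = fit_cox(inc, ["x"])
        assert abs(fit.beta["x"]) < 2 * fit.robust_se["x"]

    def test_common_weight_scaling_leaves_beta_unchanged(self):
        inc = _cohort(2, 4000, log_hr=0.3)
        f1 = fit_cox(inc, ["x"])
        inc2 = inc.assign(weight=2.0)
        f2 = fit_cox(inc2, ["x"])
        assert f2.beta["x"] == pytest.approx(f1.beta["x"], abs=1e-8)

    def test_no_events_is_degenerate(self):
        inc = _cohort(3, 200)
        inc["event"] = 0
        with pytest.raises(DegenerateError):
            fit_cox(inc, ["x"])

    def test_constant_predictor_rejected(self):
        inc = _cohort(4, 500)
        inc["c"] = 1.0
        with pytest.raises(ValidationError):
            fit_cox(inc, ["c"])

    def test_baseline_cumhaz_nondecreasing_with_event_time_jumps(self):
        inc = _cohort(5, 5000, log_hr=0.2)
        fit = fit_cox(inc, ["x"])
        event_ages = set(np.round(inc.loc[inc["event"] == 1, "exit_age"], 9))
        for stratum, bh in fit.baseline_cumhaz.items():
            assert (np.diff(bh["cumhaz"]) >= 0).all()
            assert set(np.round(bh["time"], 9)) <= event_ages

    def test_schoenfeld_null_p_is_roughly_uniform(self):
        ps = []
        for s in range(25):
            inc = _cohort(100 + s, 1500, log_hr=0.3)
            ps.append(fit_cox(inc, ["x"]).schoenfeld_p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestHrPerSd:
    def test_zero_beta_is_unit_hazard(self):
        res = CoxResult(
            beta=pd.Series({"x": 0.0}), robust_se=pd.Series({"x": 0.1}),
            covariance=pd.DataFrame([[0.01]], index=["x"], columns=["x"]),
            baseline_cumhaz={}, norm_mean=pd.Series({"x": 0.0}),
            schoenfeld_p=1.0, loglik=0.0, predictors=["x"],
        )
        hr, _ = hr_per_sd(res, "x")
        assert hr == 1.0

    def test_closed_form_ci(self):
        res = CoxResult(
            beta=pd.Series({"x": np.log(2)}), robust_se=pd.Series({"x": 0.0}),
            covariance=pd.DataFrame([[0.0]], index=["x"], columns=["x"]),
            baseline_cumhaz={}, norm_mean=pd.Series({"x": 0.0}),
            schoenfeld_p=1.0, loglik=0.0, predictors=["x"],
        )
        hr, (lo, hi) = hr_per_sd(res, "x")
        assert hr == pytest.approx(2.0)
        assert (lo, hi) == (pytest.approx(2.0), pytest.approx(2.0))


class TestPercentileBins:
    def test_monotone_risk_orders_extreme_bins(self):
        inc = _cohort(6, 20_000, log_hr=0.5)
        spec = PercentileBinSpec(edges=(0.0, 0.10, 0.45, 0.55, 0.90, 1.0), reference=2)
        table = percentile_bin_hr(inc["x"].to_numpy(), inc, spec)
        hr_bottom = table.loc[table["bin"] == 0, "hr"].iloc[0]
        hr_top = table.loc[table["bin"] == 4, "hr"].iloc[0]
        assert hr_top > 1 > hr_bottom
        assert table.loc[table["bin"] == 2, "hr"].iloc[0] == 1.0

    def test_null_score_bins_cover_unity(self):
        inc = _cohort(7, 8000)
        table = percentile_bin_hr(inc["x"].to_numpy(), inc)
        off_ref = table[table["bin"] != 2]
        cover = (off_ref["ci_low"] <= 1.0) & (1.0 <= off_ref["ci_high"])
        assert cover.mean() >= 0.75

    def test_empty_bin_rejected(self):
        inc = _cohort(8, 50)
        spec = PercentileBinSpec(edges=(0.0, 0.001, 0.45, 0.55, 1.0), reference=2)
        with pytest.raises(ValidationError):
            percentile_bin_hr(np.zeros(len(inc)), inc, spec)


class TestHarrellC:
    def test_perfect_ranking_on_events_only_toy(self):
        rec = pd.DataFrame(
            {
                "entry_age": [0.0] * 3, "exit_age": [2.0, 4.0, 7.0],
                "event": [1, 1, 1],
            }
        )
        c, _ = harrell_c(rec, np.array([5.0, 4.0, 2.0]))
        assert c == 1.0

    def test_worked_five_record_fixture_matches_oracle(self):
        rec = pd.DataFrame(
            {
                "entry_age": [0.0] * 5,
                "exit_age": [2.0, 4.0, 5.0, 7.0, 9.0],
                "event": [1, 1, 0, 1, 0],
            }
        )
        score = np.array([5.0, 4.0, 3.0, 2.0, 1.0])
        c, _ = harrell_c(rec, score)
        oracle = harrell_c_oracle(
            rec["entry_age"].to_numpy(), rec["exit_age"].to_numpy(),
            rec["event"].to_numpy().astype(bool), score,
        )
        assert c == pytest.approx(oracle) == 1.0

    def test_random_score_is_near_half(self):
        inc = _cohort(9, 5000, log_hr=0.4)
        rng = np.random.default_rng(0)
        c, (lo, hi) = harrell_c(inc, rng.normal(size=len(inc)))
        assert lo <= 0.5 <= hi

    def test_matches_oracle_on_left_truncated_fixtures(self):
        for seed in range(4):
            rng = np.random.default_rng(seed)
            n = 40
            rec = pd.DataFrame(
                {
                    "entry_age": rng.uniform(40, 60, n),
                }
            )
            rec["exit_age"] = rec["entry_age"] + rng.uniform(0.5, 20, n)
            rec["event"] = rng.integers(0, 2, n)
            if rec["event"].sum() == 0:
                rec.loc[0, "event"] = 1
            score = rng.choice(np.arange(10).astype(float), size=n)  # force score ties
            c, _ = harrell_c(rec, score)
            oracle = harrell_c_oracle(
                rec["entry_age"].to_numpy(), rec["exit_age"].to_numpy(),
                rec["event"].to_numpy().astype(bool), score,
            )
            assert c == pytest.approx(oracle, abs=1e-12)

    def test_no_comparable_pairs_rejected(self):
        rec = pd.DataFrame({"entry_age": [0.0], "exit_age": [1.0], "event": [1]})
        with pytest.raises(ValidationError):
            harrell_c(rec, np.array([1.0]))


class TestKaplanMeier:
    def test_no_events_keeps_survival_at_one(self):
        rec = pd.DataFrame(
            {"entry_age": [40.0, 50.0], "exit_age": [70.0, 75.0], "event": [0, 0]}
        )
        curves, p = kaplan_meier(rec, np.array(["a", "a"]))
        assert (curves["a"]["survival"] == 1.0).all()

    def test_logrank_null_p_is_roughly_uniform(self):
        ps = []
        for s in range(120):
            rng = np.random.default_rng(1000 + s)
            inc = _cohort(2000 + s, 600, log_hr=0.0)
            groups = rng.integers(0, 2, len(inc))
            _, p = kaplan_meier(inc, groups)
            ps.append(p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_logrank_detects_true_group_hazard_difference(self):
        hits = 0
        for s in range(5):
            rng = np.random.default_rng(3000 + s)
            g = rng.integers(0, 2, 4000)
            rec = simulate_survival(np.log(2) * g, rng)
            keep = (rec["prevalent"] == 0).to_numpy()
            _, p = kaplan_meier(rec.loc[keep].reset_index(drop=True), g[keep])
            hits += p < 0.001
        assert hits >= 4

    def test_empty_group_rejected(self):
        rec = pd.DataFrame({"entry_age": [40.0], "exit_age": [70.0], "event": [1]})
        with pytest.raises(ValidationError):
            kaplan_meier(rec, np.array([], dtype=str))


class TestCumulativeIncidence:
    def test_zero_linear_predictor_equals_baseline(self):
        inc = _cohort(10, 8000, log_hr=0.3)
        fit = fit_cox(inc, ["x"])
        with pytest.warns(UserWarning):
            out = cumulative_incidence(fit, {"x": float(fit.norm_mean["x"])}, [70.0, 75.0])
        for stratum, bh in fit.baseline_cumhaz.items():
            h70 = bh.loc[bh["time"] <= 70.0, "cumhaz"].iloc[-1]
            got = out.loc[(out["stratum"] == stratum) & (out["time"] == 70.0), "risk"].iloc[0]
            assert got == pytest.approx(1 - np.exp(-h70), rel=1e-10)

    def test_before_first_event_risk_is_zero(self):
        inc = _cohort(11, 3000, log_hr=0.2)
        fit = fit_cox(inc, ["x"])
        out = cumulative_incidence(fit, {"x": 0.0}, [1.0])
        assert (out["risk"] == 0.0).all()

    def test_monotone_in_time_and_linear_predictor(self):
        inc = _cohort(12, 8000, log_hr=0.3)
        fit = fit_cox(inc, ["x"])
        lo = cumulative_incidence(fit, {"x": -1.0}, [60.0, 65.0, 70.0])
        hi = cumulative_incidence(fit, {"x": 1.0}, [60.0, 65.0, 70.0])
        for stratum in lo["stratum"].unique():
            a = lo.loc[lo["stratum"] == stratum, "risk"].to_numpy()
            b = hi.loc[hi["stratum"] == stratum, "risk"].to_numpy()
            assert (np.diff(a) >= 0).all()
            assert (b >= a).all()

    def test_missing_profile_entry_rejected(self):
        inc = _cohort(13, 2000, log_hr=0.2)
        fit = fit_cox(inc, ["x"])
        with pytest.raises(ValidationError):
            cumulative_incidence(fit, {}, [70.0])


class TestCalibration:
    def test_identical_predictions_collapse_to_single_bin(self, rng):
        p = np.full(500, 0.1)
        y = rng.binomial(1, p)
        table = calibration_by_decile(p, y, rate_ratio=1.0)
        assert len(table) == 1
        assert table["observed"].iloc[0] == pytest.approx(y.mean())

    def test_rate_ratio_acts_on_odds_scale(self, rng):
        p = np.full(10, 0.01)
        t1 = calibration_by_decile(p, np.zeros(10), rate_ratio=1.0)
        t2 = calibration_by_decile(p, np.zeros(10), rate_ratio=2.0)
        # odds 0.0101 halved -> p ~ 0.00503
        assert t2["mean_predicted"].iloc[0] == pytest.approx(
            t1["mean_predicted"].iloc[0] / 2, rel=0.01
        )

    def test_invalid_rate_ratio_rejected(self):
        with pytest.raises(ValidationError):
            calibration_by_decile(np.array([0.1]), np.array([0]), rate_ratio=0.0)


def _liability_factor_oracle(K, P, b=1e-4):
    """Numerical threshold-model integration, independent of the closed form."""
    t = stats.norm.ppf(1 - K)
    s = np.sqrt(1 - b**2)
    gs = np.linspace(-8, 8, 20_001)
    fg = stats.norm.pdf(gs)
    py1 = stats.norm.sf((t - b * gs) / s)
    c_case, c_ctrl = P / K, (1 - P) / (1 - K)
    w1 = fg * py1 * c_case
    w0 = fg * (1 - py1) * c_ctrl
    dz = gs[1] - gs[0]
    tot = (w1 + w0).sum() * dz
    Ey = w1.sum() * dz / tot
    Eg = ((w1 + w0) * gs).sum() * dz / tot
    Eg2 = ((w1 + w0) * gs**2).sum() * dz / tot
    Egy = (w1 * gs).sum() * dz / tot
    cov = Egy - Eg * Ey
    r2_obs = cov**2 / ((Eg2 - Eg**2) * (Ey * (1 - Ey)))
    return b**2 / r2_obs


class TestLiabilityScale:
    def test_zero_r2_maps_to_zero(self):
        assert r2_to_liability(0.0, LiabilityParams(K=0.1, P=0.1)) == 0.0

    def test_p_equals_k_reduces_to_classic_factor(self):
        for K in (0.008, 0.05, 0.5):
            t = stats.norm.ppf(1 - K)
            z = stats.norm.pdf(t)
            classic = K * (1 - K) / z**2
            assert liability_factor(K, K) == pytest.approx(classic, abs=1e-12)

    def test_half_prevalence_closed_form(self):
        # K = P = 0.5: factor = 0.25 / phi(0)^2 = pi/2
        got = liability_factor(0.5, 0.5)
        assert got == pytest.approx(0.25 / stats.norm.pdf(0.0) ** 2, rel=1e-12)
        assert got == pytest.approx(np.pi / 2, abs=1e-12)

    def test_matches_numerical_threshold_model_oracle(self):
        got = liability_factor(0.008, 0.074)
        oracle = _liability_factor_oracle(0.008, 0.074)
        assert got == pytest.approx(oracle, rel=1e-6)

    def test_ascertained_variant_close_to_linear_for_small_r2(self):
        params = LiabilityParams(K=0.008, P=0.074)
        lin = r2_to_liability(1e-4, params, method="linear")
        asc = r2_to_liability(1e-4, params, method="ascertained")
        assert asc == pytest.approx(lin, rel=0.05)

    def test_degenerate_prevalence_rejected(self):
        with pytest.raises(ValidationError):
            LiabilityParams(K=0.0, P=0.1)


class TestExplainedHeritability:
    def test_zero_numerator(self):
        assert (explained_heritability(0.0, [0.1, 0.4]) == 0.0).all()

    def test_simple_division_and_grid_ratio(self):
        frac = explained_heritability(0.008, [0.1, 0.4])
        assert frac.iloc[0] == pytest.approx(0.08)
        assert frac.iloc[0] / frac.iloc[1] == pytest.approx(4.0)

    def test_invalid_h2_rejected(self):
        with pytest.raises(ValidationError):
            explained_heritability(0.01, [0.0])


class TestInteraction:
    def test_null_interaction_p_uniform_logistic(self):
        ps = []
        for s in range(60):
            rng = np.random.default_rng(5000 + s)
            n = 1500
            a = rng.standard_normal(n)
            b = rng.integers(0, 2, n).astype(float)
            y = rng.binomial(1, 1 / (1 + np.exp(-(0.5 * a + 0.3 * b - 2.0))))
            df = pd.DataFrame({"a": a, "b": b, "event": y})
            ps.append(interaction_wald_p(df, "a", "b", model="logistic"))
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_strong_interaction_detected_in_cox(self):
        hits = 0
        for s in range(5):
            rng = np.random.default_rng(6000 + s)
            n = 20_000
            a = rng.standard_normal(n)
            b = rng.integers(0, 2, n).astype(float)
            rec = simulate_survival(0.1 * a + 0.1 * b + 0.5 * a * b, rng)
            rec["a"], rec["b"] = a, b
            inc = rec.loc[rec["prevalent"] == 0].reset_index(drop=True)
            hits += interaction_wald_p(inc, "a", "b", model="cox") < 0.01
        assert hits >= 4

    def test_constant_moderator_rejected(self):
        df = pd.DataFrame(
            {"a": [0.1, 0.5, -0.2], "b": [1.0, 1.0, 1.0], "event": [0, 1, 0],
             "entry_age": [40.0] * 3, "exit_age": [50.0] * 3, "sex": ["M", "F", "M"]}
        )
        with pytest.raises(ValidationError):
            interaction_wald_p(df, "a", "b")
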