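"""Synthetic cohort generation with the statistical structure the method assumes.

The generator produces LD-blocked hard-call genotypes, K genetically
correlated trait architectures with chosen heritabilities, external
GWAS summary statistics of stated sample size (independent of the
target cohort, as when component scores are built from consortium
meta-analyses that exclude the validation biobank), vascular risk
factors with medication adjustment rules, and left-truncated survival
outcomes on the age time scale with administrative censoring at 75 and
an event-oversampled derivation/validation split.

Genotypes are unphased hard calls drawn by thresholding exchangeably
correlated latent normals at Hardy–Weinberg cut points — sufficient for
dosage-r² pruning, with no recombination-map or coalescent realism.
All draws flow from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .genotypes import GenotypeMatrix
from .sumstats import SumStats

__all__ = [
    "TraitSpec",
    "ArchitectureSpec",
    "SimCohort",
    "simulate_genotypes",
    "simulate_architecture",
    "liabilities_from_effects",
    "simulate_sumstats",
    "simulate_risk_factors",
    "derive_risk_factors",
    "simulate_survival",
    "split_oversampled",
    "simulate_study",
]

#: administrative censoring age (years)
ADMIN_CAP = 75.0


@dataclass(frozen=True)
class TraitSpec:
    label: str
    h2: float
    causal_fraction: float = 0.1

    def __post_init__(self) -> None:
        if not (0.0 <= self.h2 < 1.0):
            raise ValidationError(f"h2 must lie in [0, 1), got {self.h2}")
        if not (0.0 < self.causal_fraction <= 1.0):
            raise ValidationError("causal_fraction must lie in (0, 1]")


@dataclass
class ArchitectureSpec:
    """Genotype panel layout and multi-trait genetic architecture."""

    n_variants: int
    block_sizes: list
    within_block_r: float
    maf_range: tuple = (0.05, 0.5)
    traits: list = field(default_factory=list)
    genetic_corr: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.block_sizes) != self.n_variants:
            raise ValidationError("block sizes must sum to n_variants")
        if not (0.0 <= self.within_block_r < 1.0):
            raise ValidationError("within_block_r must lie in [0, 1)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValidationError("maf_range must lie within (0, 0.5]")
        K = len(self.traits)
        if self.genetic_corr is None and K:
            self.genetic_corr = np.eye(K)
        if K:
            R = np.asarray(self.genetic_corr, dtype=float)
            if R.shape != (K, K) or not np.allclose(R, R.T) or not np.allclose(np.diag(R), 1.0):
                raise ValidationError("genetic_corr must be symmetric with unit diagonal")
            if np.linalg.eigvalsh(R).min() < -1e-10:
                raise ValidationError("genetic_corr must be positive semi-definite")
            self.genetic_corr = R


def _variant_frame(spec: ArchitectureSpec, rng: np.random.Generator) -> tuple[pd.DataFrame, np.ndarray]:
    block_mafs = rng.uniform(*spec.maf_range, size=len(spec.block_sizes))
    mafs = np.repeat(block_mafs, spec.block_sizes)
    pos, chrom = [], []
    p = 1
    for b, size in enumerate(spec.block_sizes):
        for _ in range(size):
            pos.append(p)
            chrom.append("1")
            p += 1_000  # 1 kb spacing within a block
        p += 2_000_000  # large gap between blocks
    variants = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": np.asarray(pos, dtype=np.int64),
            "id": [f"rs{i + 1}" for i in range(spec.n_variants)],
            "ea": "A",
            "oa": "G",
        }
    )
    return variants, mafs


def simulate_genotypes(
    spec: ArchitectureSpec, n_samples: int, rng: np.random.Generator | None = None
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Draw an LD-blocked dosage matrix; returns ``(genotypes, mafs)``.

    Variants within a block share one MAF (tightly linked variants have
    matched frequencies) and an exchangeable latent-normal correlation;
    each latent is discretized to {0, 1, 2} at the Hardy–Weinberg cut
    points, so the dosage counts the effect allele at the block's MAF.
    Discretization attenuates correlation, so the shared-factor loading
    is compensated by the analytic latent-to-dosage attenuation factor:
    ``within_block_r`` then approximates the *dosage* correlation
    within a block (capped where hard calls cannot reach it).
    Deterministic under the spec seed.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    variants, mafs = _variant_frame(spec, rng)
    n = n_samples
    r = spec.within_block_r
    dosages = np.empty((n, spec.n_variants), dtype=np.float32)
    j0 = 0
    for size in spec.block_sizes:
        p = float(mafs[j0])
        t0 = stats.norm.ppf((1.0 - p) ** 2)
        t1 = stats.norm.ppf((1.0 - p) ** 2 + 2.0 * p * (1.0 - p))
        if r > 0:
            # corr(dosage, latent) under HWE thresholds
            atten = (stats.norm.pdf(t0) + stats.norm.pdf(t1)) / np.sqrt(
                2.0 * p * (1.0 - p)
            )
            c = min(0.99, np.sqrt(r) / atten)
            Z = c * rng.standard_normal((n, 1)) + np.sqrt(1.0 - c**2) * rng.standard_normal(
                (n, size)
            )
        else:
            Z = rng.standard_normal((n, size))
        dosages[:, j0 : j0 + size] = (Z > t0).astype(np.float32) + (Z > t1)
        j0 += size
    return GenotypeMatrix([f"S{i + 1}" for i in range(n)], variants, dosages), mafs


def simulate_architecture(
    spec: ArchitectureSpec, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Draw raw per-allele effects; returns ``(effects m x K, causal_mask m x K)``.

    Effect vectors across traits are drawn per variant from a
    multivariate normal with correlation ``genetic_corr`` (Cholesky
    construction), then masked to each trait's causal subset;
    non-causal effects are exactly zero.  Causal subsets are nested
    prefixes of one shared permutation of the variants, so traits with
    equal causal fractions share their causal set and the stated
    genetic correlations are realized rather than diluted by
    non-overlapping causal loci.  A trait with h2 = 0 gets an all-zero
    effect vector.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    K = len(spec.traits)
    m = spec.n_variants
    for t in spec.traits:
        if t.causal_fraction * m < 1:
            raise ValidationError(f"trait {t.label}: causal set would be empty")
    L = np.linalg.cholesky(spec.genetic_corr + 1e-12 * np.eye(K))
    effects = rng.standard_normal((m, K)) @ L.T
    pool = rng.permutation(m)
    mask = np.zeros((m, K), dtype=bool)
    for k, t in enumerate(spec.traits):
        if t.h2 == 0.0:
            continue
        n_causal = max(1, int(round(t.causal_fraction * m)))
        mask[pool[:n_causal], k] = True
    effects = np.where(mask, effects, 0.0)
    return effects, mask


def liabilities_from_effects(
    genotypes: GenotypeMatrix,
    effects: np.ndarray,
    traits: list,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Build per-trait liabilities; returns ``(liabilities, genetic_values, alphas)``.

    Each trait's genetic value ``G = X beta`` is standardized to
    variance h2 on the cohort, independent N(0, 1-h2) environmental
    noise is added, and the per-allele effects are rescaled to the same
    liability units (``alphas``), so realized heritability matches the
    spec by construction.
    """
    X = genotypes.dosages.astype(np.float64)
    n, m = X.shape
    K = len(traits)
    liab = np.empty((n, K))
    gvals = np.empty((n, K))
    alphas = np.zeros((m, K))
    for k, t in enumerate(traits):
        if t.h2 == 0.0 or not np.any(effects[:, k]):
            gvals[:, k] = 0.0
            liab[:, k] = rng.standard_normal(n)
            continue
        G = X @ effects[:, k]
        sd = G.std(ddof=0)
        scale = np.sqrt(t.h2) / sd
        gvals[:, k] = (G - G.mean()) * scale
        alphas[:, k] = effects[:, k] * scale
        liab[:, k] = gvals[:, k] + np.sqrt(1.0 - t.h2) * rng.standard_normal(n)
    labels = [t.label for t in traits]
    return (
        pd.DataFrame(liab, columns=labels),
        pd.DataFrame(gvals, columns=labels),
        alphas,
    )


def simulate_sumstats(
    alphas: np.ndarray,
    mafs: np.ndarray,
    variants: pd.DataFrame,
    gwas_n: int,
    trait: str,
    rng: np.random.Generator,
) -> SumStats:
    """Emulate an external GWAS of ``gwas_n`` samples for one trait.

    Estimated effects are the true liability-scale effects plus
    sampling noise with SE ``1 / sqrt(2 n p (1-p))``; p-values come
    from the two-sided Wald statistic.  The draw is independent of any
    target cohort, mirroring a no-sample-overlap design.
    """
    if gwas_n < 100:
        raise ValidationError("gwas_n must be >= 100")
    se = 1.0 / np.sqrt(2.0 * gwas_n * mafs * (1.0 - mafs))
    alpha_hat = alphas + rng.normal(0.0, se)
    z = alpha_hat / se
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    df = variants[["chrom", "pos", "id", "ea", "oa"]].copy()
    df["beta"] = alpha_hat
    df["se"] = se
    df["p"] = pvals
    df["eaf"] = mafs
    return SumStats(df, trait=trait)


# Risk-factor generator defaults: first-assessment means/spreads of a large
# middle-aged European cohort (SBP mm Hg, DBP mm Hg, BMI kg/m2, LDL mmol/L)
# with medication and smoking rates to match.
RISK_FACTOR_DEFAULTS = {
    "sbp_mean": 140.0,
    "sbp_sd": 20.0,
    "dbp_mean": 82.0,
    "dbp_sd": 10.0,
    "bmi_mean": 27.4,
    "bmi_sd": 4.8,
    "ldl_mean": 3.6,
    "ldl_sd": 0.87,
    "smoker_rate": 0.10,
    "diabetes_rate": 0.047,
    "bp_med_rate": 0.205,
    "lipid_med_rate": 0.169,
    "record_flag_rate": 0.02,
}


def simulate_risk_factors(
    n: int, rng: np.random.Generator, liability: np.ndarray | None = None
) -> pd.DataFrame:
    """Draw raw risk factors and medication flags.

    ``liability`` (standardized) optionally shifts SBP/BMI so that
    genetic risk and measured factors correlate, as they do in real
    cohorts.  Medication flags are more likely at higher measured
    values, so the +15 mm Hg / +1.5 mmol/L adjustments act on the right
    tail as intended.
    """
    d = RISK_FACTOR_DEFAULTS
    lia = np.zeros(n) if liability is None else np.asarray(liability)
    sbp = d["sbp_mean"] + 3.0 * lia + rng.normal(0.0, d["sbp_sd"], n)
    dbp = d["dbp_mean"] + 0.35 * (sbp - d["sbp_mean"]) + rng.normal(0.0, 7.0, n)
    bmi = d["bmi_mean"] + 0.5 * lia + rng.normal(0.0, d["bmi_sd"], n)
    ldl = d["ldl_mean"] + rng.normal(0.0, d["ldl_sd"], n)
    p_bp = np.clip(d["bp_med_rate"] + 0.008 * (sbp - d["sbp_mean"]), 0.01, 0.95)
    p_lip = np.clip(d["lipid_med_rate"] + 0.10 * (ldl - d["ldl_mean"]), 0.01, 0.95)
    return pd.DataFrame(
        {
            "sbp": sbp,
            "dbp": dbp,
            "bmi": bmi,
            "ldl": ldl,
            "smoker": rng.binomial(1, d["smoker_rate"], n),
            "diabetes": rng.binomial(1, d["diabetes_rate"], n),
            "bp_med": rng.binomial(1, p_bp),
            "lipid_med": rng.binomial(1, p_lip),
            "record_flag": rng.binomial(1, d["record_flag_rate"], n),
        }
    )


def derive_risk_factors(cohort: pd.DataFrame) -> pd.DataFrame:
    """Apply the measurement adjustment and hypertension derivation rules.

    SBP gets +15 mm Hg for individuals on BP-lowering medication and
    LDL +1.5 mmol/L on lipid-lowering medication (medication masks the
    untreated value).  Hypertension is the expanded rule: on BP
    medication, or SBP > 140 mm Hg, or DBP > 90 mm Hg, or a
    hospital-record flag.
    """
    for c in ("bp_med", "lipid_med"):
        if c not in cohort.columns or cohort[c].isna().any():
            raise ValidationError(f"derive_risk_factors requires complete {c!r} flags")
    out = cohort.copy()
    out["sbp_adjusted"] = out["sbp"] + 15.0 * out["bp_med"]
    out["ldl_adjusted"] = out["ldl"] + 1.5 * out["lipid_med"]
    record = out["record_flag"] if "record_flag" in out.columns else 0
    out["hypertension"] = (
        (out["bp_med"] == 1) | (out["sbp"] > 140.0) | (out["dbp"] > 90.0) | (record == 1)
    ).astype(int)
    return out


#: Gompertz baseline giving a realistic age-rising stroke hazard with a
#: cumulative baseline incidence of about 5% by the administrative cap.
DEFAULT_GOMPERTZ = (2.8e-6, 0.10)  # (rate b, shape c): h0(t) = b exp(c t)


def simulate_survival(
    linear_pred: np.ndarray,
    rng: np.random.Generator,
    baseline: tuple = DEFAULT_GOMPERTZ,
    entry_age: np.ndarray | None = None,
    sex: np.ndarray | None = None,
    male_log_hr: float = 0.45,
    admin_cap: float = ADMIN_CAP,
    followup_years: float | None = None,
) -> pd.DataFrame:
    """Draw left-truncated survival records under a Gompertz hazard.

    Event ages come from the proportional-hazards model
    ``h(t) = b exp(c t) exp(eta)`` with ``eta`` the per-sample linear
    predictor (log-HR units); sex enters the hazard through
    ``male_log_hr`` to mimic the higher male stroke incidence.  Entry
    ages default to Uniform(40, 69) (biobank-style recruitment); events
    before entry are flagged prevalent, exits are capped at
    ``admin_cap`` and optionally at ``entry + followup_years``.
    """
    b, c = baseline
    if b <= 0 or c <= 0:
        raise ValidationError("Gompertz baseline parameters must be positive")
    eta = np.asarray(linear_pred, dtype=float)
    n = len(eta)
    if entry_age is None:
        entry_age = rng.uniform(40.0, 69.0, n)
    if sex is None:
        sex = np.where(rng.random(n) < 0.457, "M", "F")
    eta = eta + np.where(np.asarray(sex) == "M", male_log_hr, 0.0)
    E = rng.exponential(1.0, n)
    # invert H0(T) * exp(eta) = E with H0(t) = (b/c)(exp(ct) - 1)
    event_age = np.log1p(c * E * np.exp(-eta) / b) / c
    prevalent = event_age <= entry_age
    cap = np.full(n, admin_cap)
    if followup_years is not None:
        cap = np.minimum(cap, entry_age + followup_years)
    event = (~prevalent) & (event_age <= cap)
    exit_age = np.where(event, event_age, cap)
    exit_age = np.maximum(exit_age, entry_age + 1e-6)
    return pd.DataFrame(
        {
            "sample_id": [f"S{i + 1}" for i in range(n)],
            "entry_age": entry_age,
            "exit_age": exit_age,
            "event": event.astype(int),
            "sex": sex,
            "weight": 1.0,
            "prevalent": prevalent.astype(int),
            "true_event_age": event_age,
        }
    )


def split_oversampled(
    records: pd.DataFrame,
    derivation_n: int,
    case_oversample_factor: float = 1.0,
    rng: np.random.Generator | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split into an event-enriched derivation set and its complement.

    Cases enter the derivation set with ``case_oversample_factor``
    times the control probability, normalized to hit ``derivation_n``
    in expectation.  Validation (complement) records carry
    ``weight = 1 / P(remaining in validation)`` — the inverse
    probability of selection used by the weighted Cox fits.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    if derivation_n >= len(records):
        raise ValidationError("derivation_n must be smaller than the cohort")
    ev = records["event"].to_numpy().astype(bool)
    nc, n0 = int(ev.sum()), int((~ev).sum())
    q = derivation_n / (case_oversample_factor * nc + n0)
    p_case = case_oversample_factor * q
    if p_case > 1.0:
        raise ValidationError("oversample factor implies case selection probability > 1")
    p_sel = np.where(ev, p_case, q)
    in_deriv = rng.random(len(records)) < p_sel
    deriv = records.loc[in_deriv].reset_index(drop=True)
    valid = records.loc[~in_deriv].reset_index(drop=True)
    valid = valid.assign(weight=1.0 / (1.0 - p_sel[~in_deriv]))
    return deriv, valid


@dataclass
class SimCohort:
    """Everything one simulated study provides, truth included."""

    genotypes: GenotypeMatrix
    mafs: np.ndarray
    liabilities: pd.DataFrame
    genetic_values: pd.DataFrame
    alphas: np.ndarray
    sumstats: dict
    risk_factors: pd.DataFrame
    records: pd.DataFrame
    truth: dict


def simulate_study(
    spec: ArchitectureSpec,
    n_samples: int,
    gwas_n: int | dict = 200_000,
    disease_trait: str | None = None,
    disease_log_hr: float = float(np.log(1.26)),
    seed: int | None = None,
    baseline: tuple = DEFAULT_GOMPERTZ,
    followup_years: float | None = None,
) -> SimCohort:
    """Run the full generator: genotypes, traits, GWAS, risk factors, survival.

    The disease trait (default: the first in the spec) drives the
    hazard with ``disease_log_hr`` per SD of its liability.  GWAS
    summary statistics are drawn independently per trait.
    """
    seed = spec.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    gm, mafs = simulate_genotypes(spec, n_samples, rng)
    effects, causal = simulate_architecture(spec, rng)
    liab, gvals, alphas = liabilities_from_effects(gm, effects, spec.traits, rng)
    labels = [t.label for t in spec.traits]
    disease = disease_trait or labels[0]
    sumstats = {}
    for k, lab in enumerate(labels):
        n_k = gwas_n[lab] if isinstance(gwas_n, dict) else gwas_n
        sumstats[lab] = simulate_sumstats(alphas[:, k], mafs, gm.variants, n_k, lab, rng)
    lia_std = (liab[disease] - liab[disease].mean()) / liab[disease].std(ddof=1)
    rf = simulate_risk_factors(n_samples, rng, liability=lia_std.to_numpy())
    rf = derive_risk_factors(rf)
    records = simulate_survival(
        disease_log_hr * lia_std.to_numpy(), rng, baseline=baseline,
        followup_years=followup_years,
    )
    records["sample_id"] = gm.sample_ids
    truth = {
        "disease_trait": disease,
        "disease_log_hr": disease_log_hr,
        "alphas": alphas,
        "causal": causal,
        "seed": seed,
    }
    return SimCohort(gm, mafs, liab, gvals, alphas, sumstats, rf, records, truth)
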