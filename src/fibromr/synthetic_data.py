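"""Multi-cohort synthetic data with known causal ground truth.

This module generates the two kinds of input a Mendelian-randomization
analysis of a plasma biomarker (here fibrinogen, g/L) against an incident
cardiovascular outcome needs:

* individual-level cohort data — genotype dosages under Hardy-Weinberg
  equilibrium, phenotypes (age, sex, fibrinogen, metabolic risk factors)
  and proportional-hazards survival outcomes with administrative
  censoring; and
* two-sample GWAS summary statistics — per-variant exposure and outcome
  effect estimates with standard errors derived from stated GWAS sample
  sizes, optionally contaminated by horizontal pleiotropy (balanced,
  directional, or a small set of outlier variants).

The generative model is deliberately simple and fully parameterized:

    G_ij ~ Binomial(2, p_j)                       (dosages, HWE)
    U_i  ~ N(0, 1)                                (unobserved confounder)
    F_i  = c0 + sum_j beta_j G_ij + gamma_U U_i
              + a_age (age_i - 60) + a_sex sex_i + N(0, sigma_F^2)
    h_i(t) = lambda_0 exp(theta F_i + delta_U U_i + sum_j alpha_j G_ij)

with exponential event times and administrative censoring.  theta is the
causal log-hazard (one-sample) or log-odds (two-sample) per 1 g/L of
fibrinogen; alpha_j are direct variant->outcome (pleiotropic) effects.
Because the same confounder U raises both fibrinogen and the hazard, a
naive Cox regression of the outcome on measured fibrinogen is biased,
which is precisely what the instrumented analyses are meant to avoid.

All randomness flows from one explicit seed through per-purpose
``numpy.random.SeedSequence`` spawn keys; identical (config, seed) pairs
give bit-identical outputs and no global generator state is touched.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SimConfig",
    "CohortData",
    "RISK_FACTOR_COLUMNS",
    "pleiotropy_effects",
    "simulate_cohort",
    "simulate_summary_stats",
    "simulate_risk_factor_correlated_variant",
    "to_interval_censoring",
    "variant_panel",
    "split_summary_tables",
]

#: risk-factor columns carried by every simulated cohort (smoking is coded
#: ordinal: 0 never < 1 former < 2 current)
RISK_FACTOR_COLUMNS = ("bmi", "ldl", "hdl", "hypertension", "diabetes", "smoking")

_PLEIOTROPY_MODES = ("none", "balanced", "directional", "outliers")

# spawn-key namespaces for the per-purpose random streams
_STREAM_COHORT = 0
_STREAM_SUMMARY = 1
_STREAM_COPULA = 2
_STREAM_ALPHA = 3


@dataclass
class SimConfig:
    """Generative truth for one simulated study.

    Defaults emulate the scale of a multi-cohort incident-CHD study: ~30
    instrument variants with per-allele fibrinogen effects of 0.02-0.08
    g/L, fibrinogen residual SD 0.6 g/L, a baseline hazard giving roughly
    10-15%% cumulative incidence over 12 years of follow-up, and
    two-sample GWAS sizes of 120,000 (exposure) and 184,305 (outcome,
    i.e. 60,801 cases + 123,504 controls).
    """

    n_individuals: int = 5000
    n_cohorts: int = 6
    n_variants: int = 30
    effect_allele_freqs: np.ndarray | None = None
    variant_exposure_effects: np.ndarray | None = None
    causal_effect: float = 0.25
    pleiotropy_mode: str = "none"
    pleiotropy_mean: float = 0.05
    pleiotropy_sd: float = 0.02
    balanced_pleiotropy_sd: float = 0.05
    n_outliers: int = 2
    outlier_scale: float = 10.0
    outlier_alpha: float | None = None
    confounder_effect_on_exposure: float = 0.3
    confounder_effect_on_outcome: float = 0.3
    baseline_hazard: float = 0.005
    censoring_time_max: float = 12.0
    noise_sd: float = 0.6
    age_effect: float = 0.01
    sex_effect: float = -0.1
    fibrinogen_intercept: float = 2.6
    n_exposure_gwas: int = 120_000
    n_outcome_gwas: int = 184_305
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals <= 0:
            raise ValueError("n_individuals must be positive")
        if self.n_cohorts <= 0:
            raise ValueError("n_cohorts must be positive")
        if self.n_variants <= 0:
            raise ValueError("n_variants must be positive")
        if self.pleiotropy_mode not in _PLEIOTROPY_MODES:
            raise ValueError(
                f"pleiotropy_mode must be one of {_PLEIOTROPY_MODES}, "
                f"got {self.pleiotropy_mode!r}"
            )
        if self.effect_allele_freqs is None:
            self.effect_allele_freqs = np.linspace(0.1, 0.5, self.n_variants)
        self.effect_allele_freqs = np.asarray(self.effect_allele_freqs, dtype=float)
        if self.effect_allele_freqs.shape != (self.n_variants,):
            raise ValueError("effect_allele_freqs must have length n_variants")
        if np.any(self.effect_allele_freqs <= 0) or np.any(self.effect_allele_freqs >= 1):
            raise ValueError("allele frequencies must lie strictly inside (0, 1)")
        if self.variant_exposure_effects is None:
            self.variant_exposure_effects = np.linspace(0.02, 0.08, self.n_variants)
        self.variant_exposure_effects = np.asarray(
            self.variant_exposure_effects, dtype=float
        )
        if self.variant_exposure_effects.shape != (self.n_variants,):
            raise ValueError("variant_exposure_effects must have length n_variants")
        scalars = (
            self.causal_effect,
            self.confounder_effect_on_exposure,
            self.confounder_effect_on_outcome,
            self.baseline_hazard,
            self.censoring_time_max,
            self.noise_sd,
            self.age_effect,
            self.sex_effect,
            self.fibrinogen_intercept,
        )
        if not all(math.isfinite(s) for s in scalars):
            raise ValueError("all scalar parameters must be finite")
        if not np.all(np.isfinite(self.effect_allele_freqs)) or not np.all(
            np.isfinite(self.variant_exposure_effects)
        ):
            raise ValueError("all vector parameters must be finite")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be > 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.pleiotropy_mode == "outliers" and not (
            0 <= self.n_outliers <= self.n_variants
        ):
            raise ValueError("n_outliers must lie in [0, n_variants]")

    def variant_ids(self) -> list[str]:
        width = max(3, len(str(self.n_variants)))
        return [f"snp{j + 1:0{width}d}" for j in range(self.n_variants)]

    def replace(self, **changes) -> "SimConfig":
        return dataclasses.replace(self, **changes)


@dataclass
class CohortData:
    """One cohort's individual-level data.

    ``dosages``  — individuals x variants, values in [0, 2], NaN allowed.
    ``phenotypes`` — age (y), sex (1 = male), fibrinogen (g/L) plus the
    six risk-factor columns of :data:`RISK_FACTOR_COLUMNS`.
    ``outcomes`` — right-censored: ``event`` (0/1) and ``time`` (years);
    interval-censored: ``left``/``right`` bounds of the interval (left,
    right] containing the event time (``right`` = inf when censored).
    """

    dosages: pd.DataFrame
    phenotypes: pd.DataFrame
    outcomes: pd.DataFrame
    censor_type: str = "right"
    label: str = ""

    def __post_init__(self) -> None:
        if self.censor_type not in ("right", "interval"):
            raise ValueError("censor_type must be 'right' or 'interval'")
        vals = self.dosages.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            if np.any((vals < 0) | (vals > 2)):
                raise ValueError("dosages must lie within [0, 2] where present")
        if self.censor_type == "right":
            if np.any(self.outcomes["time"].to_numpy() < 0):
                raise ValueError("follow-up times must be non-negative")
        else:
            left = self.outcomes["left"].to_numpy()
            right = self.outcomes["right"].to_numpy()
            if np.any(left < 0) or np.any(left >= right):
                raise ValueError("interval bounds must satisfy 0 <= left < right")

    @property
    def n(self) -> int:
        return len(self.phenotypes)


def _rng(seed: int, *spawn_key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=spawn_key))


def pleiotropy_effects(config: SimConfig) -> np.ndarray:
    """Direct variant->outcome effects alpha_j implied by the config.

    Drawn from a dedicated random stream so that cohort-level and
    summary-level simulations of the same config share the same alpha.
    ``none`` gives all zeros; ``balanced`` is mean-zero normal;
    ``directional`` is normal around ``pleiotropy_mean`` (independent of
    beta_j, so the InSIDE condition holds by construction); ``outliers``
    leaves all but ``n_outliers`` variants at zero and gives those a
    direct effect ``outlier_scale`` times the typical variant-level
    outcome effect, alternating in sign.
    """
    rng = _rng(config.seed, _STREAM_ALPHA)
    m = config.n_variants
    alpha = np.zeros(m)
    if config.pleiotropy_mode == "balanced":
        alpha = rng.normal(0.0, config.balanced_pleiotropy_sd, m)
    elif config.pleiotropy_mode == "directional":
        alpha = rng.normal(config.pleiotropy_mean, config.pleiotropy_sd, m)
    elif config.pleiotropy_mode == "outliers":
        idx = rng.choice(m, size=config.n_outliers, replace=False)
        if config.outlier_alpha is not None:
            magnitude = config.outlier_alpha
        else:
            typical = np.median(
                np.abs(config.causal_effect * config.variant_exposure_effects)
            )
            if typical == 0:  # null causal effect: anchor to the outcome SE scale
                typical = float(np.median(_summary_se_outcome(config)))
            magnitude = config.outlier_scale * typical
        signs = np.where(np.arange(config.n_outliers) % 2 == 0, 1.0, -1.0)
        alpha[np.sort(idx)] = magnitude * signs
    return alpha


def outlier_variant_ids(config: SimConfig) -> list[str]:
    """Variant ids carrying planted outlier pleiotropy (empty unless mode='outliers')."""
    if config.pleiotropy_mode != "outliers":
        return []
    alpha = pleiotropy_effects(config)
    ids = np.asarray(config.variant_ids())
    return [str(v) for v in ids[alpha != 0]]


def _draw_phenotypes(rng: np.random.Generator, n: int, u: np.ndarray) -> pd.DataFrame:
    """Risk factors and demographics; independent of genotype by design.

    BMI loads on the latent confounder U so that adiposity-style
    confounding of the fibrinogen-outcome relation is visible in the
    observational (non-instrumented) analysis.
    """
    age = rng.normal(60.0, 8.0, n)
    sex = rng.integers(0, 2, n).astype(float)
    bmi = 27.0 + 1.5 * u + rng.normal(0.0, 4.5, n)
    ldl = rng.normal(127.0, 37.0, n)
    hdl = rng.normal(53.0, 16.0, n)
    hypertension = rng.binomial(1, 0.3, n).astype(float)
    diabetes = rng.binomial(1, 0.12, n).astype(float)
    smoking = rng.choice(3, size=n, p=[0.45, 0.32, 0.23]).astype(float)
    return pd.DataFrame(
        {
            "age": age,
            "sex": sex,
            "bmi": bmi,
            "ldl": ldl,
            "hdl": hdl,
            "hypertension": hypertension,
            "diabetes": diabetes,
            "smoking": smoking,
        }
    )


def _hwe_bins(p: float) -> tuple[float, float]:
    """Cumulative genotype-class probabilities under HWE for one variant."""
    q = 1.0 - p
    return q * q, q * q + 2.0 * p * q


def _generate_cohort(
    config: SimConfig,
    rng: np.random.Generator,
    coupled: tuple[int, float] | None = None,
    label: str = "",
) -> CohortData:
    n, m = config.n_individuals, config.n_variants
    p = config.effect_allele_freqs
    beta = config.variant_exposure_effects
    alpha = pleiotropy_effects(config)

    dosages = rng.binomial(2, p, size=(n, m)).astype(float)
    u = rng.standard_normal(n)
    pheno = _draw_phenotypes(rng, n, u)

    if coupled is not None:
        # Gaussian copula between one designated variant and BMI: the
        # variant's dosage is re-drawn from a latent normal correlated at
        # `latent_r` with the latent driving BMI's idiosyncratic part.
        j, latent_r = coupled
        z1 = rng.standard_normal(n)
        z2 = latent_r * z1 + math.sqrt(1.0 - latent_r**2) * rng.standard_normal(n)
        lo, hi = _hwe_bins(p[j])
        uquant = stats.norm.cdf(z1)
        dosages[:, j] = np.where(uquant < lo, 0.0, np.where(uquant < hi, 1.0, 2.0))
        pheno["bmi"] = 27.0 + 1.5 * u + 4.5 * z2

    fib = (
        config.fibrinogen_intercept
        + dosages @ beta
        + config.confounder_effect_on_exposure * u
        + config.age_effect * (pheno["age"].to_numpy() - 60.0)
        + config.sex_effect * pheno["sex"].to_numpy()
        + rng.normal(0.0, config.noise_sd, n)
    )
    pheno.insert(2, "fibrinogen", fib)

    log_hr = (
        config.causal_effect * fib
        + config.confounder_effect_on_outcome * u
        + dosages @ alpha
    )
    rate = config.baseline_hazard * np.exp(log_hr)
    event_time = rng.exponential(1.0 / rate)
    cmax = config.censoring_time_max
    event = (event_time <= cmax).astype(int)
    time = np.minimum(event_time, cmax)
    outcomes = pd.DataFrame({"event": event, "time": time})

    ids = config.variant_ids()
    return CohortData(
        dosages=pd.DataFrame(dosages, columns=ids),
        phenotypes=pheno,
        outcomes=outcomes,
        censor_type="right",
        label=label,
    )


def simulate_cohort(config: SimConfig, cohort_index: int) -> CohortData:
    """Simulate one cohort; deterministic given (config.seed, cohort_index)."""
    if not 0 <= cohort_index:
        raise ValueError("cohort_index must be non-negative")
    rng = _rng(config.seed, _STREAM_COHORT, cohort_index)
    return _generate_cohort(config, rng, label=f"cohort{cohort_index + 1}")


def _summary_se_exposure(config: SimConfig) -> np.ndarray:
    p = config.effect_allele_freqs
    return config.noise_sd / np.sqrt(2.0 * p * (1.0 - p) * config.n_exposure_gwas)


def _summary_se_outcome(config: SimConfig) -> np.ndarray:
    p = config.effect_allele_freqs
    return 1.0 / np.sqrt(2.0 * p * (1.0 - p) * config.n_outcome_gwas)


_ALLELE_CYCLE = (("A", "G"), ("C", "T"), ("G", "A"), ("T", "C"))


def simulate_summary_stats(config: SimConfig) -> pd.DataFrame:
    """Two-sample GWAS summary statistics for every variant.

    Exposure estimates are drawn around the true beta_j; outcome
    estimates around theta*beta_j + alpha_j.  Standard errors follow the
    standard GWAS approximation se = s / sqrt(2 p (1-p) n) with s the
    trait SD for the exposure and 1 (standardized log-odds) for the
    outcome.  Returns one harmonized row per variant with columns
    variant_id, effect_allele, other_allele, eaf, beta_exposure,
    se_exposure, beta_outcome, se_outcome.
    """
    rng = _rng(config.seed, _STREAM_SUMMARY)
    beta = config.variant_exposure_effects
    alpha = pleiotropy_effects(config)
    se_exp = _summary_se_exposure(config)
    se_out = _summary_se_outcome(config)
    beta_hat = beta + rng.standard_normal(config.n_variants) * se_exp
    gamma_hat = (
        config.causal_effect * beta
        + alpha
        + rng.standard_normal(config.n_variants) * se_out
    )
    alleles = [_ALLELE_CYCLE[j % len(_ALLELE_CYCLE)] for j in range(config.n_variants)]
    return pd.DataFrame(
        {
            "variant_id": config.variant_ids(),
            "effect_allele": [a for a, _ in alleles],
            "other_allele": [b for _, b in alleles],
            "eaf": config.effect_allele_freqs,
            "beta_exposure": beta_hat,
            "se_exposure": se_exp,
            "beta_outcome": gamma_hat,
            "se_outcome": se_out,
        }
    )


def split_summary_tables(
    pairs: pd.DataFrame, swap_every: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split harmonized pairs into separate exposure and outcome GWAS tables.

    With ``swap_every`` = k > 0 every k-th outcome row is recorded on the
    opposite allele (labels swapped, effect negated, frequency reflected),
    which is exactly what allele harmonization must undo.
    """
    exposure = pairs[
        ["variant_id", "effect_allele", "other_allele", "eaf", "beta_exposure", "se_exposure"]
    ].rename(columns={"beta_exposure": "beta", "se_exposure": "se"})
    outcome = pairs[
        ["variant_id", "effect_allele", "other_allele", "eaf", "beta_outcome", "se_outcome"]
    ].rename(columns={"beta_outcome": "beta", "se_outcome": "se"})
    outcome = outcome.copy()
    if swap_every > 0:
        mask = np.arange(len(outcome)) % swap_every == 0
        ea = outcome.loc[mask, "effect_allele"].copy()
        outcome.loc[mask, "effect_allele"] = outcome.loc[mask, "other_allele"].to_numpy()
        outcome.loc[mask, "other_allele"] = ea.to_numpy()
        outcome.loc[mask, "beta"] = -outcome.loc[mask, "beta"]
        outcome.loc[mask, "eaf"] = 1.0 - outcome.loc[mask, "eaf"]
    return exposure.reset_index(drop=True), outcome.reset_index(drop=True)


def _calibrate_latent_r(p: float, target_rho: float, seed: int) -> float:
    """Monotone bisection for the latent normal correlation that yields the
    requested Spearman correlation between the binned dosage and BMI.

    Uses common random numbers (one large calibration draw reused at every
    bisection step) so the empirical Spearman is monotone in the latent r.
    """
    if target_rho == 0.0:
        return 0.0
    rng = _rng(seed, _STREAM_COPULA, 0)
    n_cal = 200_000
    z1 = rng.standard_normal(n_cal)
    e2 = rng.standard_normal(n_cal)
    eb = rng.standard_normal(n_cal)
    lo, hi = _hwe_bins(p)
    uq = stats.norm.cdf(z1)
    g = np.where(uq < lo, 0.0, np.where(uq < hi, 1.0, 2.0))

    def empirical(latent_r: float) -> float:
        z2 = latent_r * z1 + math.sqrt(1.0 - latent_r**2) * e2
        bmi = 1.5 * eb + 4.5 * z2
        rho, _ = stats.spearmanr(g, bmi)
        return float(rho)

    lo_r, hi_r = (0.0, 0.999) if target_rho > 0 else (-0.999, 0.0)
    for _ in range(16):
        mid = 0.5 * (lo_r + hi_r)
        if empirical(mid) < target_rho:
            lo_r = mid
        else:
            hi_r = mid
    return 0.5 * (lo_r + hi_r)


def simulate_risk_factor_correlated_variant(
    config: SimConfig, target_rho: float, cohort_index: int = 0, variant_index: int = 0
) -> CohortData:
    """Cohort in which one designated variant's dosage has population
    Spearman correlation ~ ``target_rho`` with BMI (Gaussian copula).

    Used to exercise the risk-factor correlation screen: a variant built
    with |rho| > 0.10 must be removed by the filter.
    """
    if not abs(target_rho) < 1:
        raise ValueError("|target_rho| must be < 1")
    latent_r = _calibrate_latent_r(
        float(config.effect_allele_freqs[variant_index]), target_rho, config.seed
    )
    rng = _rng(config.seed, _STREAM_COPULA, 1, cohort_index)
    return _generate_cohort(
        config, rng, coupled=(variant_index, latent_r), label=f"copula{cohort_index + 1}"
    )


def to_interval_censoring(cohort: CohortData, width: float = 1.0) -> CohortData:
    """Convert a right-censored cohort to interval-censored outcomes.

    Events are recorded only as lying in (time - width/2, time + width/2]
    intersected with [0, inf); censored individuals keep an open interval
    (time, inf).  ``width`` ~ the spacing between follow-up examinations.
    """
    if cohort.censor_type != "right":
        raise ValueError("cohort is already interval-censored")
    if width <= 0:
        raise ValueError("width must be > 0")
    time = cohort.outcomes["time"].to_numpy(dtype=float)
    event = cohort.outcomes["event"].to_numpy(dtype=int)
    left = np.where(event == 1, np.maximum(time - width / 2.0, 0.0), time)
    right = np.where(event == 1, time + width / 2.0, np.inf)
    # guard the degenerate left == right case for events at t = 0
    right = np.where(right <= left, left + width, right)
    outcomes = pd.DataFrame({"left": left, "right": right, "event": event})
    return CohortData(
        dosages=cohort.dosages.copy(),
        phenotypes=cohort.phenotypes.copy(),
        outcomes=outcomes,
        censor_type="interval",
        label=cohort.label,
    )


def variant_panel(config: SimConfig) -> pd.DataFrame:
    """Published-association panel for the config's variants.

    One row per variant with the fields the instrument-construction step
    consumes: alleles, published per-allele fibrinogen effect and SE,
    source study with a sample-size rank, and an imputation-quality value
    (all 1.0: the QC filter is exercised through explicit tables in
    tests).  Source studies cycle so LD pruning has ranks to choose by.
    """
    betas = config.variant_exposure_effects
    se = _summary_se_exposure(config)
    sources = ["gwas_large", "gwas_medium", "exome_small"]
    ranks = {"gwas_large": 3, "gwas_medium": 2, "exome_small": 1}
    alleles = [_ALLELE_CYCLE[j % len(_ALLELE_CYCLE)] for j in range(config.n_variants)]
    rows = []
    for j, vid in enumerate(config.variant_ids()):
        src = sources[j % 3]
        rows.append(
            {
                "variant_id": vid,
                "chr": 1 + j % 22,
                "pos": 1_000_000 + 50_000 * j,
                "effect_allele": alleles[j][0],
                "other_allele": alleles[j][1],
                "beta": betas[j],
                "se": se[j],
                "source_study": src,
                "source_rank": ranks[src],
            }
        )
    return pd.DataFrame(rows)
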