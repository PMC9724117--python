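"""Synthetic cohort generator emulating the Ndlovu baseline risk-factor
structure.

Marginals default to the published sex-specific baseline characteristics
(age, BMI, lipids, blood pressure means/SDs; smoking, diabetes, treatment,
family-history, ART prevalences; CD4 median/IQR), so the overall mixture
reproduces the published overall column. Continuous variables are drawn
through a Gaussian copula with modest rank correlations (the joint structure
is not published and is an explicit modelling invention); truncated-normal
marginals are moment-matched numerically so truncation does not bias the
configured means. Blood-pressure missingness is injected separately, MCAR or
MAR with logistic dependence on age and sex, hitting the target fraction
exactly (weighted sampling without replacement).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .cohort import CohortTable

__all__ = [
    "TruncNormBySex",
    "MissingnessConfig",
    "GeneratorConfig",
    "GeneratorError",
    "generate",
    "inject_missingness",
]


class GeneratorError(ValueError):
    pass


@dataclass(frozen=True)
class TruncNormBySex:
    """Target mean/SD per sex of a truncated-normal marginal on [lower, upper]."""

    male: tuple[float, float]
    female: tuple[float, float]
    lower: float
    upper: float


@dataclass(frozen=True)
class MissingnessConfig:
    fraction: float = 0.616          # share of BP readings from the non-validated device
    mechanism: str = "MAR"           # "MCAR" | "MAR"
    beta_age: float = 0.03           # log-odds per year of age
    beta_female: float = 0.2         # log-odds for female sex


@dataclass
class GeneratorConfig:
    n: int = 735
    seed: int = 20141101
    female_fraction: float = 0.567
    age: TruncNormBySex = TruncNormBySex((46.1, 9.2), (42.2, 8.2), 30.0, 75.0)
    bmi: TruncNormBySex = TruncNormBySex((21.2, 4.3), (25.4, 6.3), 14.0, 55.0)
    sbp: TruncNormBySex = TruncNormBySex((116.1, 14.5), (114.6, 17.06), 80.0, 220.0)
    dbp: TruncNormBySex = TruncNormBySex((75.0, 9.0), (73.4, 10.4), 40.0, 130.0)
    total_chol: TruncNormBySex = TruncNormBySex((4.1, 1.0), (4.5, 1.01), 1.5, 12.0)
    hdl_chol: TruncNormBySex = TruncNormBySex((1.4, 0.5), (1.5, 0.4), 0.4, 5.0)
    smoking_current: dict = field(default_factory=lambda: {"male": 0.428, "female": 0.082})
    smoking_ex: float = 0.10
    diabetes: float = 0.035
    bp_treated: float = 0.035
    family_history: dict = field(default_factory=lambda: {"male": 0.135, "female": 0.201})
    on_art: float = 0.867
    abacavir_among_art: float = 0.025
    indinavir: tuple[float, float] = (0.03, 2.0)   # (prevalence among ART, mean years)
    lopinavir: tuple[float, float] = (0.10, 2.5)
    cd4_median: float = 469.0
    cd4_sigma: float = 0.551                        # matches published IQR 312-656
    established_cvd: float = 0.02
    race: str = "black"
    #: Spearman rank correlations of the latent Gaussian copula
    rank_correlations: dict = field(default_factory=lambda: {
        ("age", "sbp"): 0.30,
        ("age", "dbp"): 0.20,
        ("age", "total_chol"): 0.20,
        ("bmi", "sbp"): 0.25,
        ("bmi", "dbp"): 0.20,
        ("sbp", "dbp"): 0.70,
    })
    missingness: MissingnessConfig = field(default_factory=MissingnessConfig)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise GeneratorError("n must be >= 1")
        for frac in (self.female_fraction, self.diabetes, self.bp_treated,
                     self.on_art, self.missingness.fraction):
            if not 0.0 <= frac <= 1.0:
                raise GeneratorError(f"fraction out of [0,1]: {frac}")


_COPULA_VARS = ("age", "bmi", "sbp", "dbp", "total_chol", "hdl_chol", "cd4")


@lru_cache(maxsize=256)
def _matched_truncnorm(mean: float, sd: float, lower: float, upper: float):
    """Underlying (mu, sigma) so the [lower, upper]-truncated normal has the
    target mean and SD."""

    def moments(params):
        mu, log_sigma = params
        sigma = np.exp(log_sigma)
        a, b = (lower - mu) / sigma, (upper - mu) / sigma
        m, v = stats.truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
        return [m - mean, np.sqrt(v) - sd]

    sol = optimize.fsolve(moments, [mean, np.log(sd)], full_output=False)
    mu, sigma = float(sol[0]), float(np.exp(sol[1]))
    return mu, sigma


def _truncnorm_ppf(u: np.ndarray, spec: TruncNormBySex, male: np.ndarray) -> np.ndarray:
    out = np.empty(len(u))
    for is_male, (mean, sd) in ((True, spec.male), (False, spec.female)):
        mask = male if is_male else ~male
        if not mask.any():
            continue
        mu, sigma = _matched_truncnorm(mean, sd, spec.lower, spec.upper)
        a, b = (spec.lower - mu) / sigma, (spec.upper - mu) / sigma
        out[mask] = stats.truncnorm.ppf(u[mask], a, b, loc=mu, scale=sigma)
    return out


def _copula_correlation(config: GeneratorConfig) -> np.ndarray:
    k = len(_COPULA_VARS)
    r = np.eye(k)
    idx = {v: i for i, v in enumerate(_COPULA_VARS)}
    for (a, b), rho_s in config.rank_correlations.items():
        # Spearman -> Pearson on the latent Gaussian scale
        rho = 2.0 * np.sin(np.pi * rho_s / 6.0)
        i, j = idx[a], idx[b]
        r[i, j] = r[j, i] = rho
    eig = np.linalg.eigvalsh(r)
    if eig.min() < -1e-10:
        raise GeneratorError(
            f"infeasible correlation matrix (min eigenvalue {eig.min():.3g})")
    return r


def generate(config: GeneratorConfig | None = None, **overrides) -> CohortTable:
    """Generate a complete synthetic cohort (no missing blood pressure; use
    :func:`inject_missingness` for the MAR missingness stage)."""
    if config is None:
        config = GeneratorConfig(**overrides)
    elif overrides:
        config = dataclasses.replace(config, **overrides)
    rng = np.random.default_rng(config.seed)
    n = config.n

    female = rng.random(n) < config.female_fraction
    male = ~female
    sex = np.where(female, "female", "male")

    corr = _copula_correlation(config)
    chol_factor = np.linalg.cholesky(corr)
    z = (chol_factor @ rng.standard_normal((len(_COPULA_VARS), n))).T
    u = stats.norm.cdf(z)

    cols = {}
    for i, var in enumerate(_COPULA_VARS[:-1]):
        cols[var] = _truncnorm_ppf(u[:, i], getattr(config, var), male)
    cd4 = np.exp(np.log(config.cd4_median) + config.cd4_sigma * z[:, -1])

    # enforce HDL < total cholesterol by resampling violators from the
    # admissible quantile range (correlation for these few rows is sacrificed)
    tc, hdl = cols["total_chol"], cols["hdl_chol"]
    bad = hdl >= tc
    if bad.any():
        spec = config.hdl_chol
        for is_male in (True, False):
            mask = bad & (male if is_male else female)
            if not mask.any():
                continue
            mu, sigma = _matched_truncnorm(*(spec.male if is_male else spec.female),
                                           spec.lower, spec.upper)
            a, b = (spec.lower - mu) / sigma, (spec.upper - mu) / sigma
            cap = stats.truncnorm.cdf(0.9 * tc[mask], a, b, loc=mu, scale=sigma)
            hdl[mask] = stats.truncnorm.ppf(rng.random(mask.sum()) * cap, a, b,
                                            loc=mu, scale=sigma)
    cols["hdl_chol"] = np.minimum(hdl, 0.95 * tc)

    p_smoke = np.where(male, config.smoking_current["male"],
                       config.smoking_current["female"])
    u_smoke = rng.random(n)
    smoking = np.where(u_smoke < p_smoke, "current",
                       np.where(u_smoke < p_smoke + config.smoking_ex, "ex", "never"))

    diabetes = rng.random(n) < config.diabetes
    hba1c = np.where(
        diabetes,
        np.maximum(6.6, rng.normal(7.8, 1.0, n)),
        np.minimum(6.4, rng.normal(5.4, 0.5, n)),
    )
    bp_treated = rng.random(n) < config.bp_treated
    famhist = rng.random(n) < np.where(male, config.family_history["male"],
                                       config.family_history["female"])
    on_art = rng.random(n) < config.on_art
    abacavir = on_art & (rng.random(n) < config.abacavir_among_art)
    idv_prev, idv_mean = config.indinavir
    lpv_prev, lpv_mean = config.lopinavir
    idv = np.where(on_art & (rng.random(n) < idv_prev),
                   rng.exponential(idv_mean, n), 0.0)
    lpv = np.where(on_art & (rng.random(n) < lpv_prev),
                   rng.exponential(lpv_mean, n), 0.0)
    established = rng.random(n) < config.established_cvd

    frame = pd.DataFrame({
        "id": [f"P{i:06d}" for i in range(n)],
        "age": cols["age"],
        "sex": sex,
        "sbp": cols["sbp"],
        "dbp": cols["dbp"],
        "bp_treated": bp_treated,
        "total_chol": cols["total_chol"],
        "hdl_chol": cols["hdl_chol"],
        "smoking": smoking,
        "diabetes": diabetes,
        "hba1c": hba1c,
        "bmi": cols["bmi"],
        "family_history_cvd": famhist,
        "on_art": on_art,
        "cd4_latest": cd4,
        "exposure_years_pi_indinavir": idv,
        "exposure_years_pi_lopinavir": lpv,
        "abacavir_current": abacavir,
        "established_cvd": established,
        "bp_device_validated": True,
        "race": config.race,
    })
    return CohortTable(frame, provenance=f"synthetic(seed={config.seed}, n={n})")


def inject_missingness(
    cohort: CohortTable,
    fraction: float,
    mechanism: str = "MAR",
    seed: int = 20141101,
    beta_age: float = 0.03,
    beta_female: float = 0.2,
) -> tuple[CohortTable, pd.DataFrame]:
    """Null out blood pressure for exactly ``round(fraction * n)`` records.

    Under MAR the selection log-odds rise linearly with age and are shifted
    for women; MCAR selects uniformly. Returns the masked cohort plus a
    truth table (id, sbp, dbp, masked flag) for recovery tests - callers
    keep it out of the main cohort file.
    """
    if not 0.0 <= fraction <= 1.0:
        raise GeneratorError(f"fraction must lie in [0,1], got {fraction}")
    frame = cohort.frame.copy()
    n = len(frame)
    truth = frame[["id", "sbp", "dbp"]].copy()
    k = int(round(fraction * n))
    rng = np.random.default_rng(seed)
    if mechanism == "MCAR":
        logw = np.zeros(n)
    elif mechanism == "MAR":
        age = frame["age"].to_numpy(float)
        female = (frame["sex"] == "female").to_numpy(float)
        logw = beta_age * (age - age.mean()) + beta_female * female
    else:
        raise GeneratorError(f"unknown mechanism {mechanism!r}")
    # Gumbel top-k == weighted sampling without replacement
    keys = logw + rng.gumbel(size=n)
    chosen = np.argsort(keys)[::-1][:k]
    mask = np.zeros(n, dtype=bool)
    mask[chosen] = True
    frame.loc[mask, ["sbp", "dbp"]] = np.nan
    frame["bp_device_validated"] = ~mask
    truth["masked"] = mask
    return CohortTable(frame, cohort.provenance), truth
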