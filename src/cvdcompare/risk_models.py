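"""Coefficient-table-driven CVD risk scoring engines.

Five models are registered:

``FHS_CVD``
    Framingham general cardiovascular disease equation (2008), lipid variant,
    sex-stratified, 10-year Cox form ``risk = 1 - S0^exp(L - mean_lp)``.
``FHS_CHD``
    Framingham coronary heart disease equation (1998), risk-factor-category
    form, sex-stratified, 10-year Cox form.
``ASCVD``
    Pooled cohort atherosclerotic CVD equations (2013), sex x race strata,
    10-year Cox form.
``DAD_2010`` / ``DAD_2016``
    HIV-specific 5-year models in Poisson rate form
    ``risk = 1 - exp(-h * baseline * exp(sum beta (x - center)))``; the 2016
    full model additionally uses the latest CD4 count (log2, protective).

Coefficients live in versioned plain-text data files shipped with the
package (``cvdcompare/data``); each carries a provenance header, keeping the
equations auditable and models addable without code change. Lipid unit
conversion (mmol/L -> mg/dL, factor 38.67) happens here, never in the cohort
layer.
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass
from enum import Enum
from importlib import resources
from typing import Callable

import numpy as np
import pandas as pd
import yaml

from .cohort import CohortTable, ParticipantRecord

__all__ = [
    "ModelID",
    "RiskCategory",
    "Term",
    "StratumCoefficients",
    "ModelCoefficients",
    "RiskEstimate",
    "ScoringError",
    "load_coefficients",
    "available_models",
    "score_cohort",
    "score_cox_form",
    "score_dad",
    "extrapolate_risk",
    "categorize_risk",
]

MGDL_PER_MMOL = 38.67  # cholesterol unit conversion


class ModelID(str, Enum):
    FHS_CVD = "FHS_CVD"
    FHS_CHD = "FHS_CHD"
    ASCVD = "ASCVD"
    DAD_2010 = "DAD_2010"
    DAD_2016 = "DAD_2016"


class RiskCategory(str, Enum):
    LOW = "low"
    MODERATE = "moderate"
    HIGH = "high"


class ScoringError(ValueError):
    """A variable required by a model is unavailable, or input is invalid."""


@dataclass(frozen=True)
class Term:
    variable: str
    transform: str
    coefficient: float
    center: float | None
    unit: str


@dataclass
class StratumCoefficients:
    terms: list[Term]
    s0: float | None = None           # Cox form baseline survival
    mean_lp: float | None = None      # Cox form centering constant
    baseline_rate: float | None = None  # rate form, events per person-year


@dataclass
class ModelCoefficients:
    model_id: ModelID
    form: str                          # "cox" | "rate"
    horizon_years: int
    stratum_by: str                    # "sex" | "sex_race" | "none"
    age_range: tuple[float, float]
    strata: dict[str, StratumCoefficients]


@dataclass
class RiskEstimate:
    model_id: ModelID
    horizon_years: float
    probability: float
    category: RiskCategory
    extrapolated: bool = False
    age_out_of_range: bool = False


# ---------------------------------------------------------------------------
# feature registry: variable name in the coefficient files -> vectorized
# evaluation on a canonical cohort frame; second element lists the raw
# cohort columns the feature needs (for null diagnostics).

def _smoker(df: pd.DataFrame) -> np.ndarray:
    return (df["smoking"] == "current").to_numpy(float)


def _ln_sbp(df: pd.DataFrame) -> np.ndarray:
    return np.log(df["sbp"].to_numpy(float))


def _treated(df: pd.DataFrame) -> np.ndarray:
    return df["bp_treated"].to_numpy(float)


def _bp_category(df: pd.DataFrame) -> np.ndarray:
    """JNC-V blood-pressure stage 0..4; the higher of the SBP and DBP stage."""
    sbp = df["sbp"].to_numpy(float)
    dbp = df["dbp"].to_numpy(float)
    s = np.select([sbp < 120, sbp < 130, sbp < 140, sbp < 160], [0, 1, 2, 3], 4)
    d = np.where(np.isnan(dbp), 0,
                 np.select([dbp < 80, dbp < 85, dbp < 90, dbp < 100], [0, 1, 2, 3], 4))
    return np.maximum(s, d)


def _cat_indicator(cat_fn: Callable, level: int) -> Callable:
    return lambda df: (cat_fn(df) == level).astype(float)


def _tc_mgdl_cat(df: pd.DataFrame) -> np.ndarray:
    tc = df["total_chol"].to_numpy(float) * MGDL_PER_MMOL
    return np.select([tc < 160, tc < 200, tc < 240, tc < 280], [0, 1, 2, 3], 4)


def _hdl_mgdl_cat(df: pd.DataFrame) -> np.ndarray:
    hdl = df["hdl_chol"].to_numpy(float) * MGDL_PER_MMOL
    return np.select([hdl < 35, hdl < 45, hdl < 50, hdl < 60], [0, 1, 2, 3], 4)


FEATURES: dict[str, tuple[Callable[[pd.DataFrame], np.ndarray], tuple[str, ...]]] = {
    "age": (lambda df: df["age"].to_numpy(float), ("age",)),
    "age_sq": (lambda df: df["age"].to_numpy(float) ** 2, ("age",)),
    "age_per5": (lambda df: df["age"].to_numpy(float) / 5.0, ("age",)),
    "ln_age": (lambda df: np.log(df["age"].to_numpy(float)), ("age",)),
    "ln_age_sq": (lambda df: np.log(df["age"].to_numpy(float)) ** 2, ("age",)),
    "ln_tc": (lambda df: np.log(df["total_chol"].to_numpy(float) * MGDL_PER_MMOL),
              ("total_chol",)),
    "ln_hdl": (lambda df: np.log(df["hdl_chol"].to_numpy(float) * MGDL_PER_MMOL),
               ("hdl_chol",)),
    "ln_age_x_ln_tc": (lambda df: np.log(df["age"].to_numpy(float))
                       * np.log(df["total_chol"].to_numpy(float) * MGDL_PER_MMOL),
                       ("age", "total_chol")),
    "ln_age_x_ln_hdl": (lambda df: np.log(df["age"].to_numpy(float))
                        * np.log(df["hdl_chol"].to_numpy(float) * MGDL_PER_MMOL),
                        ("age", "hdl_chol")),
    "ln_sbp_treated": (lambda df: _ln_sbp(df) * _treated(df), ("sbp", "bp_treated")),
    "ln_sbp_untreated": (lambda df: _ln_sbp(df) * (1.0 - _treated(df)),
                         ("sbp", "bp_treated")),
    "ln_age_x_ln_sbp_treated": (
        lambda df: np.log(df["age"].to_numpy(float)) * _ln_sbp(df) * _treated(df),
        ("age", "sbp", "bp_treated")),
    "ln_age_x_ln_sbp_untreated": (
        lambda df: np.log(df["age"].to_numpy(float)) * _ln_sbp(df) * (1.0 - _treated(df)),
        ("age", "sbp", "bp_treated")),
    "smoker": (_smoker, ("smoking",)),
    "ln_age_x_smoker": (lambda df: np.log(df["age"].to_numpy(float)) * _smoker(df),
                        ("age", "smoking")),
    "diabetes": (lambda df: df["diabetes"].to_numpy(float), ("diabetes",)),
    # D:A:D rate-form features (native mmol/L units)
    "male": (lambda df: (df["sex"] == "male").to_numpy(float), ("sex",)),
    "smoke_current": (lambda df: (df["smoking"] == "current").to_numpy(float), ("smoking",)),
    "smoke_ex": (lambda df: (df["smoking"] == "ex").to_numpy(float), ("smoking",)),
    "family_history": (lambda df: df["family_history_cvd"].to_numpy(float),
                       ("family_history_cvd",)),
    "sbp_per10": (lambda df: df["sbp"].to_numpy(float) / 10.0, ("sbp",)),
    "tc_mmol": (lambda df: df["total_chol"].to_numpy(float), ("total_chol",)),
    "hdl_mmol": (lambda df: df["hdl_chol"].to_numpy(float), ("hdl_chol",)),
    "cd4_log2": (lambda df: np.log2(df["cd4_latest"].to_numpy(float)), ("cd4_latest",)),
    "indinavir_years": (lambda df: df["exposure_years_pi_indinavir"].to_numpy(float),
                        ("exposure_years_pi_indinavir",)),
    "lopinavir_years": (lambda df: df["exposure_years_pi_lopinavir"].to_numpy(float),
                        ("exposure_years_pi_lopinavir",)),
    "abacavir_current": (lambda df: df["abacavir_current"].to_numpy(float),
                         ("abacavir_current",)),
}

_TC_LEVELS = ["lt160", "160_199", "200_239", "240_279", "ge280"]
_HDL_LEVELS = ["lt35", "35_44", "45_49", "50_59", "ge60"]
_BP_LEVELS = ["optimal", "normal", "highnormal", "stage1", "stage2"]
for _i, _lvl in enumerate(_TC_LEVELS):
    FEATURES[f"tc_cat_{_lvl}"] = (_cat_indicator(_tc_mgdl_cat, _i), ("total_chol",))
for _i, _lvl in enumerate(_HDL_LEVELS):
    FEATURES[f"hdl_cat_{_lvl}"] = (_cat_indicator(_hdl_mgdl_cat, _i), ("hdl_chol",))
for _i, _lvl in enumerate(_BP_LEVELS):
    FEATURES[f"bp_cat_{_lvl}"] = (_cat_indicator(_bp_category, _i), ("sbp",))


# ---------------------------------------------------------------------------
# registry / coefficient loading

def _data_text(name: str) -> str:
    return resources.files("cvdcompare.data").joinpath(name).read_text()


_REGISTRY_CACHE: dict | None = None


def _registry() -> dict:
    global _REGISTRY_CACHE
    if _REGISTRY_CACHE is None:
        _REGISTRY_CACHE = yaml.safe_load(_data_text("registry.yaml"))
    return _REGISTRY_CACHE


def available_models() -> list[ModelID]:
    return [ModelID(m) for m in _registry()]


def load_coefficients(model_id: ModelID | str) -> ModelCoefficients:
    """Load one model's coefficient table and baseline constants."""
    model_id = ModelID(model_id)
    entry = _registry()[model_id.value]
    table = pd.read_csv(io.StringIO(_data_text(entry["file"])), comment="#")
    strata: dict[str, StratumCoefficients] = {}
    for key, const in entry["strata"].items():
        rows = table[table["stratum"] == key]
        terms = []
        for r in rows.itertuples(index=False):
            if r.variable not in FEATURES:
                raise ScoringError(f"{model_id.value}: unknown variable {r.variable!r}")
            center = None if pd.isna(r.center) else float(r.center)
            terms.append(Term(r.variable, r.transform, float(r.coefficient),
                              center, "" if pd.isna(r.unit) else str(r.unit)))
        strata[key] = StratumCoefficients(
            terms=terms,
            s0=const.get("s0"),
            mean_lp=const.get("mean_lp"),
            baseline_rate=const.get("baseline_rate"),
        )
        s = strata[key]
        if entry["form"] == "cox" and not (s.s0 is not None and 0 < s.s0 < 1):
            raise ScoringError(f"{model_id.value}/{key}: S0 must lie in (0,1)")
    return ModelCoefficients(
        model_id=model_id,
        form=entry["form"],
        horizon_years=int(entry["horizon_years"]),
        stratum_by=entry["stratum_by"],
        age_range=tuple(entry["age_range"]),
        strata=strata,
    )


# ---------------------------------------------------------------------------
# scoring

def _check_nulls(df: pd.DataFrame, coeffs: ModelCoefficients) -> None:
    needed: set[str] = set()
    for s in coeffs.strata.values():
        for t in s.terms:
            needed.update(FEATURES[t.variable][1])
    for col in sorted(needed):
        vals = df[col]
        null = vals.isna() if vals.dtype != object else vals.isna()
        if bool(null.any()):
            ids = df.loc[null, "id"].astype(str).tolist()[:5] if "id" in df else []
            raise ScoringError(
                f"{coeffs.model_id.value}: required variable {col!r} is null"
                + (f" for ids {ids}" if ids else "")
            )


def _stratum_key(df: pd.DataFrame, coeffs: ModelCoefficients, default_race: str) -> pd.Series:
    if coeffs.stratum_by == "sex":
        return df["sex"].map({"male": "male", "female": "female"})
    if coeffs.stratum_by == "sex_race":
        race = df["race"] if "race" in df else pd.Series(default_race, index=df.index)
        race = race.fillna(default_race).replace("", default_race)
        race = race.where(race.isin(["black", "white"]), "white")  # "other" -> white set
        return race + "_" + df["sex"]
    return pd.Series("all", index=df.index)


def _linear_predictor(df: pd.DataFrame, stratum: StratumCoefficients,
                      centered: bool) -> np.ndarray:
    lp = np.zeros(len(df))
    for t in stratum.terms:
        x = FEATURES[t.variable][0](df)
        if centered:
            x = x - (t.center if t.center is not None else 0.0)
        lp += t.coefficient * x
    return lp


def score_frame(df: pd.DataFrame, coeffs: ModelCoefficients, *,
                default_race: str = "black") -> pd.DataFrame:
    """Vectorized scoring of a canonical cohort frame.

    Returns a frame with ``probability``, ``category``, ``horizon_years``,
    ``age_out_of_range`` indexed like ``df``; raises :class:`ScoringError`
    when a required variable is null or exposure years are negative.
    """
    if len(df) == 0:
        raise ScoringError(f"{coeffs.model_id.value}: empty cohort")
    for col in ("exposure_years_pi_indinavir", "exposure_years_pi_lopinavir"):
        if col in df and (df[col].to_numpy(float) < 0).any():
            raise ScoringError(f"{coeffs.model_id.value}: negative {col}")
    _check_nulls(df, coeffs)
    keys = _stratum_key(df, coeffs, default_race)
    prob = np.empty(len(df))
    for key, sub_idx in df.groupby(keys, sort=False).groups.items():
        if key not in coeffs.strata:
            raise ScoringError(f"{coeffs.model_id.value}: no stratum {key!r}")
        s = coeffs.strata[key]
        sub = df.loc[sub_idx]
        if coeffs.form == "cox":
            lp = _linear_predictor(sub, s, centered=False)
            p = 1.0 - s.s0 ** np.exp(lp - s.mean_lp)
        else:
            lp = _linear_predictor(sub, s, centered=True)
            lam = s.baseline_rate * np.exp(lp)
            p = 1.0 - np.exp(-coeffs.horizon_years * lam)
        prob[df.index.get_indexer(sub_idx)] = p
    lo, hi = coeffs.age_range
    age = df["age"].to_numpy(float)
    out = pd.DataFrame(
        {
            "probability": prob,
            "category": [categorize_risk(p).value for p in prob],
            "horizon_years": coeffs.horizon_years,
            "age_out_of_range": (age < lo) | (age > hi),
        },
        index=df.index,
    )
    return out


def score_cohort(cohort: CohortTable | pd.DataFrame, model_id: ModelID | str, *,
                 default_race: str = "black") -> pd.DataFrame:
    frame = cohort.frame if isinstance(cohort, CohortTable) else cohort
    return score_frame(frame, load_coefficients(model_id), default_race=default_race)


def _record_frame(record: ParticipantRecord) -> pd.DataFrame:
    d = dataclasses.asdict(record)
    d.pop("hypertension", None)
    d.pop("obesity", None)
    return pd.DataFrame([d])


def _single_estimate(record: ParticipantRecord, coeffs: ModelCoefficients,
                     default_race: str) -> RiskEstimate:
    res = score_frame(_record_frame(record), coeffs, default_race=default_race)
    row = res.iloc[0]
    return RiskEstimate(
        model_id=coeffs.model_id,
        horizon_years=float(coeffs.horizon_years),
        probability=float(row["probability"]),
        category=RiskCategory(row["category"]),
        extrapolated=False,
        age_out_of_range=bool(row["age_out_of_range"]),
    )


def score_cox_form(record: ParticipantRecord,
                   coeffs: ModelCoefficients | ModelID | str, *,
                   default_race: str = "black") -> RiskEstimate:
    """Score one participant with a Cox-form model (FHS-CVD, FHS-CHD, ASCVD)."""
    if not isinstance(coeffs, ModelCoefficients):
        coeffs = load_coefficients(coeffs)
    if coeffs.form != "cox":
        raise ScoringError(f"{coeffs.model_id.value} is not a Cox-form model")
    return _single_estimate(record, coeffs, default_race)


def score_dad(record: ParticipantRecord,
              coeffs: ModelCoefficients | None = None,
              version: int = 2010) -> RiskEstimate:
    """Score one participant with a D:A:D rate-form model (5-year horizon)."""
    if version not in (2010, 2016):
        raise ScoringError(f"unknown D:A:D version {version}")
    if coeffs is None:
        coeffs = load_coefficients(ModelID.DAD_2010 if version == 2010 else ModelID.DAD_2016)
    if coeffs.form != "rate":
        raise ScoringError(f"{coeffs.model_id.value} is not a rate-form model")
    return _single_estimate(record, coeffs, "black")


def categorize_risk(probability: float) -> RiskCategory:
    """Band a predicted event probability: low < 0.10 <= moderate <= 0.20 < high.

    Both band edges fall in the moderate band (closed-interval convention).
    """
    if not (0.0 <= probability <= 1.0) or not np.isfinite(probability):
        raise ScoringError(f"probability outside [0,1]: {probability}")
    if probability < 0.10:
        return RiskCategory.LOW
    if probability <= 0.20:
        return RiskCategory.MODERATE
    return RiskCategory.HIGH


def extrapolate_probability(p: float | np.ndarray, source_horizon: float,
                            target_horizon: float) -> float | np.ndarray:
    """Constant-hazard horizon scaling: ``p_T = 1 - (1 - p_t)^(T/t)``."""
    if target_horizon < source_horizon:
        raise ScoringError("target horizon shorter than source horizon")
    if np.any(np.asarray(p) >= 1.0):
        raise ScoringError("cannot extrapolate a probability of 1")
    return 1.0 - (1.0 - p) ** (target_horizon / source_horizon)


def extrapolate_risk(est: RiskEstimate, target_horizon: float) -> RiskEstimate:
    """Rescale a risk estimate to a longer horizon under a constant hazard."""
    p = extrapolate_probability(est.probability, est.horizon_years, target_horizon)
    return RiskEstimate(
        model_id=est.model_id,
        horizon_years=float(target_horizon),
        probability=float(p),
        category=categorize_risk(float(p)),
        extrapolated=target_horizon != est.horizon_years or est.extrapolated,
        age_out_of_range=est.age_out_of_range,
    )
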