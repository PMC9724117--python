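"""Chained-equations multiple imputation of blood pressure, with Rubin's-rules
pooling.

Missingness is confined to systolic/diastolic blood pressure (the study
design: readings from a non-validated device are discarded and assumed
missing at random). Each of the ``m`` imputed datasets is produced by an
independent chain: missing cells are initialised by resampling observed
values, then each target is repeatedly regressed on the predictor set plus
the other blood-pressure variable, with a fresh Bayesian posterior draw of
the regression coefficients and residual variance per sweep (the classical
"norm" elementary imputation model). Predictive-mean matching is available
as an alternative (``method="pmm"``). Observed cells are never modified, and
the whole procedure is reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import CohortTable

__all__ = [
    "ImputationSpec",
    "PooledEstimate",
    "ImputationError",
    "impute",
    "pool_rubin",
]

DEFAULT_PREDICTORS = (
    "age",
    "sex",
    "bmi",
    "smoking",
    "total_chol",
    "on_art",
)

TARGETS = ("sbp", "dbp")


class ImputationError(ValueError):
    pass


@dataclass
class ImputationSpec:
    """Settings for the chained-equations run.

    ``m`` imputed datasets (>= 2 so Rubin pooling is defined), ``iterations``
    chained sweeps per dataset, ``predictors`` drawn from the cohort columns
    (categorical ones are dummy-encoded), ``method`` in {"norm", "pmm"}.
    """

    m: int = 15
    predictors: tuple[str, ...] = DEFAULT_PREDICTORS
    iterations: int = 10
    seed: int = 20141101
    method: str = "norm"
    pmm_donors: int = 5

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ImputationError("m must be >= 2 for Rubin pooling")
        if self.iterations < 1:
            raise ImputationError("iterations must be >= 1")
        if self.method not in ("norm", "pmm"):
            raise ImputationError(f"unknown method {self.method!r}")


@dataclass
class PooledEstimate:
    """Rubin's-rules combination of per-dataset estimates."""

    point: float
    within_var: float
    between_var: float
    total_var: float
    df: float
    m: int


@dataclass
class ImputationDiagnostics:
    """Per-dataset trace of imputed-cell means, one row per sweep."""

    traces: dict[str, np.ndarray] = field(default_factory=dict)
    converged: bool = True


def _design_matrix(frame: pd.DataFrame, predictors: tuple[str, ...],
                   extra: str | None) -> np.ndarray:
    cols = [np.ones(len(frame))]
    for p in predictors:
        if p not in frame.columns:
            continue
        col = frame[p]
        if p == "sex":
            cols.append((col == "female").to_numpy(float))
        elif p == "smoking":
            cols.append((col == "current").to_numpy(float))
            cols.append((col == "ex").to_numpy(float))
        elif col.dtype == bool or col.dtype == object:
            cols.append(col.astype(bool).to_numpy(float))
        else:
            x = col.to_numpy(float)
            if np.isnan(x).any():
                # predictors must be complete; fall back to mean-fill
                x = np.where(np.isnan(x), np.nanmean(x), x)
            cols.append(x)
    if extra is not None:
        cols.append(frame[extra].to_numpy(float))
    return np.column_stack(cols)


def _bayes_draw_impute(y_obs: np.ndarray, x_obs: np.ndarray, x_mis: np.ndarray,
                       rng: np.random.Generator, method: str,
                       donors: int) -> np.ndarray:
    n, p = x_obs.shape
    if n <= p + 1:
        raise ImputationError("too few observed rows to fit the imputation model")
    xtx = x_obs.T @ x_obs
    # ridge epsilon guards collinear dummies without altering identified fits
    xtx += np.eye(p) * 1e-10 * np.trace(xtx)
    xtx_inv = np.linalg.inv(xtx)
    beta_hat = xtx_inv @ (x_obs.T @ y_obs)
    resid = y_obs - x_obs @ beta_hat
    dof = n - p
    sigma2_hat = float(resid @ resid) / dof
    sigma2_star = sigma2_hat * dof / rng.chisquare(dof)
    chol = np.linalg.cholesky(xtx_inv * sigma2_star)
    beta_star = beta_hat + chol @ rng.standard_normal(p)
    mu_mis = x_mis @ beta_star
    if method == "norm":
        return mu_mis + rng.standard_normal(len(mu_mis)) * np.sqrt(sigma2_star)
    # predictive-mean matching: draw from the nearest observed predictions
    mu_obs = x_obs @ beta_star
    out = np.empty(len(mu_mis))
    for i, m in enumerate(mu_mis):
        idx = np.argsort(np.abs(mu_obs - m))[:donors]
        out[i] = y_obs[rng.choice(idx)]
    return out


def impute(cohort: CohortTable, spec: ImputationSpec,
           return_diagnostics: bool = False):
    """Produce ``spec.m`` completed cohorts (blood pressure imputed).

    With no missing values the result is ``m`` identical copies. Raises
    :class:`ImputationError` when a target is entirely missing and no
    predictors are available.
    """
    frame = cohort.frame
    miss = {t: frame[t].isna().to_numpy() for t in TARGETS}
    diagnostics = ImputationDiagnostics()
    if not any(m.any() for m in miss.values()):
        datasets = [cohort.copy() for _ in range(spec.m)]
        return (datasets, diagnostics) if return_diagnostics else datasets

    usable = [p for p in spec.predictors if p in frame.columns]
    for t in TARGETS:
        if miss[t].all() and not usable:
            raise ImputationError(
                f"all values of {t!r} missing and no predictors available")

    seed_seq = np.random.SeedSequence(spec.seed)
    datasets = []
    for child in seed_seq.spawn(spec.m):
        rng = np.random.default_rng(child)
        work = frame.copy()
        # initialise missing cells by resampling observed values
        for t in TARGETS:
            obs = work.loc[~miss[t], t].to_numpy(float)
            if miss[t].any() and len(obs):
                work.loc[miss[t], t] = rng.choice(obs, size=int(miss[t].sum()))
        trace = {t: [] for t in TARGETS}
        for _ in range(spec.iterations):
            for t in TARGETS:
                if not miss[t].any():
                    continue
                other = TARGETS[1 - TARGETS.index(t)]
                extra = other if not frame[other].isna().all() else None
                x = _design_matrix(work, tuple(usable), extra)
                y_obs = frame.loc[~miss[t], t].to_numpy(float)
                drawn = _bayes_draw_impute(
                    y_obs, x[~miss[t]], x[miss[t]], rng, spec.method, spec.pmm_donors)
                work.loc[miss[t], t] = drawn
                trace[t].append(float(np.mean(drawn)))
        for t in TARGETS:
            tr = np.asarray(trace[t])
            diagnostics.traces.setdefault(t, []).append(tr)
            if len(tr) >= 2 and abs(tr[-1] - tr[-2]) > 0.01 * max(abs(tr[-2]), 1e-12):
                diagnostics.converged = False  # flagged, not fatal
        datasets.append(CohortTable(work, cohort.provenance))
    return (datasets, diagnostics) if return_diagnostics else datasets


def pool_rubin(estimates) -> PooledEstimate:
    """Combine per-dataset (point, variance) pairs by Rubin's rules.

    point = mean of points; W = mean of within variances; B = sample
    variance of points; total = W + (1 + 1/m) B. Degrees of freedom follow
    the classical formula (infinite when B = 0).
    """
    est = list(estimates)
    if len(est) < 2:
        raise ImputationError("need at least 2 estimates to pool")
    points = np.array([e[0] for e in est], dtype=float)
    wvars = np.array([e[1] for e in est], dtype=float)
    m = len(points)
    point = float(points.mean())
    w = float(wvars.mean())
    b = float(points.var(ddof=1))
    total = w + (1.0 + 1.0 / m) * b
    if b > 0:
        df = (m - 1) * (1.0 + w / ((1.0 + 1.0 / m) * b)) ** 2
    else:
        df = float("inf")
    return PooledEstimate(point, w, b, total, df, m)
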