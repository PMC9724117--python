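"""Inter-model agreement statistics on risk categorizations.

Cross-tabulation of paired risk categories, percent agreement, Cohen's kappa
(unweighted, linear- and quadratic-weighted) with its large-sample null
standard error, cumulative risk distributions, and age-subgroup category
summaries.

Kappa is chance-corrected agreement ``kappa = (Po - Pe) / (1 - Pe)`` where
``Po`` is the (weighted) observed proportion of agreement and ``Pe`` its
expectation under independent margins. The null standard error follows the
classical large-sample variance of weighted kappa (Fleiss-Cohen-Everitt),
so the p-value tests kappa = 0. Table totals are always derived from the
cells, never from a printed totals row.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .risk_models import RiskCategory

__all__ = [
    "CATEGORY_ORDER",
    "CrossTab",
    "AgreementResult",
    "AgreementError",
    "UndefinedKappaError",
    "cross_tabulate",
    "percent_agreement",
    "cohen_kappa",
    "kappa_weights",
    "interpret_kappa",
    "cumulative_distribution",
    "subgroup_summary",
]

CATEGORY_ORDER = ("low", "moderate", "high")


class AgreementError(ValueError):
    pass


class UndefinedKappaError(AgreementError):
    """Pe = 1: all probability mass sits in a single margin pair, so kappa's
    denominator vanishes. Distinct from kappa = 0."""


@dataclass
class CrossTab:
    """k x k contingency table of paired categories (rows = ``row_model``)."""

    row_model: str
    col_model: str
    counts: np.ndarray
    labels: tuple[str, ...] = CATEGORY_ORDER

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.labels)
        if self.counts.shape != (k, k):
            raise AgreementError(f"counts must be {k}x{k}, got {self.counts.shape}")
        if (self.counts < 0).any():
            raise AgreementError("negative cell count")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def row_margins(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_margins(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def transpose(self) -> "CrossTab":
        return CrossTab(self.col_model, self.row_model, self.counts.T, self.labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.labels),
                            columns=list(self.labels))


@dataclass
class AgreementResult:
    percent_agreement: float
    kappa: float
    scheme: str
    se: float
    p: float
    interpretation: str
    n: int


def cross_tabulate(categories_a: pd.Series, categories_b: pd.Series,
                   row_model: str = "A", col_model: str = "B") -> CrossTab:
    """Cross-tabulate two per-participant category assignments.

    Inputs are joined on their index (participant id); mismatched id sets
    raise an error listing the difference.
    """
    a, b = pd.Series(categories_a), pd.Series(categories_b)
    only_a = a.index.difference(b.index)
    only_b = b.index.difference(a.index)
    if len(only_a) or len(only_b):
        raise AgreementError(
            f"mismatched participant sets: only in A {list(only_a)[:5]}, "
            f"only in B {list(only_b)[:5]}"
        )
    b = b.loc[a.index]
    counts = np.zeros((3, 3), dtype=np.int64)
    ai = pd.Categorical(a.astype(str), categories=CATEGORY_ORDER).codes
    bi = pd.Categorical(b.astype(str), categories=CATEGORY_ORDER).codes
    if (ai < 0).any() or (bi < 0).any():
        raise AgreementError(f"categories must be in {CATEGORY_ORDER}")
    np.add.at(counts, (ai, bi), 1)
    return CrossTab(row_model, col_model, counts)


def percent_agreement(tab: CrossTab) -> float:
    """Percent of participants on the diagonal, full precision (round for
    display)."""
    if tab.total == 0:
        raise AgreementError("empty table")
    return 100.0 * float(np.trace(tab.counts)) / tab.total


def kappa_weights(k: int, scheme: str) -> np.ndarray:
    """Agreement weights w_ij (1 on the diagonal, decreasing off it)."""
    i, j = np.indices((k, k))
    d = np.abs(i - j) / (k - 1)
    if scheme == "unweighted":
        return (i == j).astype(float)
    if scheme == "linear":
        return 1.0 - d
    if scheme == "quadratic":
        return 1.0 - d**2
    raise AgreementError(f"unknown kappa scheme {scheme!r}")


def interpret_kappa(kappa: float) -> str:
    """Conventional agreement bands on the 2-decimal rounded value:
    <=0.20 poor, 0.21-0.40 fair, 0.41-0.60 moderate, 0.61-0.80 substantial,
    0.81-1.00 almost perfect."""
    r = round(kappa, 2)
    if r <= 0.20:
        return "poor"
    if r <= 0.40:
        return "fair"
    if r <= 0.60:
        return "moderate"
    if r <= 0.80:
        return "substantial"
    return "almost perfect"


def cohen_kappa(tab: CrossTab, scheme: str = "unweighted") -> AgreementResult:
    """Cohen's (weighted) kappa with null SE and two-sided p against kappa=0."""
    n = tab.total
    if n == 0:
        raise AgreementError("empty table")
    k = len(tab.labels)
    w = kappa_weights(k, scheme)
    p_obs = tab.counts / n
    pr = tab.row_margins / n
    pc = tab.col_margins / n
    po = float((w * p_obs).sum())
    pe = float((w * np.outer(pr, pc)).sum())
    if pe >= 1.0 - 1e-15:
        raise UndefinedKappaError("expected agreement is 1; kappa undefined")
    kappa = (po - pe) / (1.0 - pe)

    # Fleiss-Cohen-Everitt large-sample variance of weighted kappa under H0
    wbar_row = w @ pc          # E_j[w_ij] over the column margin
    wbar_col = pr @ w          # E_i[w_ij] over the row margin
    expect = np.outer(pr, pc)
    term = (w - (wbar_row[:, None] + wbar_col[None, :])) ** 2
    var0 = (float((expect * term).sum()) - pe**2) / (n * (1.0 - pe) ** 2)
    se = float(np.sqrt(max(var0, 0.0)))
    if se > 0:
        z = kappa / se
        p = 2.0 * float(stats.norm.sf(abs(z)))
    else:
        p = float("nan")
    return AgreementResult(
        percent_agreement=percent_agreement(tab),
        kappa=float(kappa),
        scheme=scheme,
        se=se,
        p=p,
        interpretation=interpret_kappa(float(kappa)),
        n=n,
    )


@dataclass
class CumulativeCurve:
    model_id: str
    grid: np.ndarray          # sorted probabilities
    fraction: np.ndarray      # cumulative fraction <= grid value
    median: float
    iqr: tuple[float, float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"probability": self.grid, "cumulative_fraction": self.fraction})


def cumulative_distribution(probabilities, model_id: str = "") -> CumulativeCurve:
    """Empirical cumulative distribution of predicted risks, plus median/IQR."""
    p = np.sort(np.asarray(probabilities, dtype=float))
    if p.size == 0:
        raise AgreementError("no estimates")
    frac = np.arange(1, p.size + 1) / p.size
    q1, med, q3 = np.quantile(p, [0.25, 0.5, 0.75])
    return CumulativeCurve(model_id, p, frac, float(med), (float(q1), float(q3)))


def subgroup_summary(age: pd.Series, categories: pd.DataFrame,
                     bins: list[tuple[float, float]] | None = None) -> pd.DataFrame:
    """Per-age-bin, per-model risk-category proportions (percent, summing to
    100 within each bin x model).

    ``categories`` holds one column per model of {low, moderate, high};
    ``bins`` are closed [lo, hi] intervals that must not overlap.
    """
    if bins is None:
        bins = [(30, 39), (40, 49), (50, 59), (60, 75)]
    for (a_lo, a_hi) in bins:
        if a_hi < a_lo:
            raise AgreementError(f"invalid bin ({a_lo}, {a_hi})")
    for x, y in zip(sorted(bins), sorted(bins)[1:]):
        if y[0] <= x[1]:
            raise AgreementError(f"overlapping age bins {x} and {y}")
    rows = []
    for (a_lo, a_hi) in sorted(bins):
        mask = (age >= a_lo) & (age <= a_hi)
        label = f"{a_lo:g}-{a_hi:g}"
        for model in categories.columns:
            sub = categories.loc[mask, model]
            denom = len(sub)
            for cat in CATEGORY_ORDER:
                pct = 100.0 * float((sub == cat).sum()) / denom if denom else float("nan")
                rows.append({"age_bin": label, "model": model, "category": cat,
                             "percent": pct, "n": denom})
    return pd.DataFrame(rows)
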