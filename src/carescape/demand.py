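"""Descriptive, comparative and regression analysis of the demand survey.

Covers four analyses: descriptive item/indicator means on the 1-5 Likert
scale and walking-time category proportions; one-dimensional K-means tiering
of commercial housing prices into low/medium/high; one-way ANOVA of item
scores across groups (residential type or price tier); and logistic
regression of binary demand indicators on ordinal respondent attributes,
reported as odds ratios with Wald statistics.

The logistic outcome can be a binary column already in the survey, or a
primary-indicator name, in which case the respondent's mean item score for
that indicator is dichotomized at a threshold (default 3, "generally
needed" or higher counts as demand) — the reconstruction assumption for
surveys that record only Likert responses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
import statsmodels.api as sm

from .errors import ComputationError, ValidationError
from .scales import DEFAULT_SCALES, ScaleDefinition, scales_by_name, walk_column


# ---------------------------------------------------------------------------
# descriptives

@dataclass(frozen=True)
class DemandSummary:
    item_means: dict[str, float]
    indicator_means: dict[str, float]
    overall_mean: float
    walk_proportions: dict[str, tuple[float, float, float]]


def overall_mean_from_indicators(
    indicator_means: dict[str, float] | list[float],
    item_counts: dict[str, int] | list[int],
) -> float:
    """Item-count-weighted mean of the primary-indicator means.

    Equals the unweighted mean of all item means when each indicator mean is
    itself the mean of its items.
    """
    if isinstance(indicator_means, dict):
        keys = list(indicator_means)
        means = np.array([indicator_means[k] for k in keys], dtype=float)
        counts = np.array([item_counts[k] for k in keys], dtype=float)
    else:
        means = np.asarray(indicator_means, dtype=float)
        counts = np.asarray(item_counts, dtype=float)
    return float(np.average(means, weights=counts))


def demand_summary(
    survey: pd.DataFrame,
    scales: tuple[ScaleDefinition, ...] = DEFAULT_SCALES,
) -> DemandSummary:
    """Item and indicator means plus walking-time category proportions."""
    items = [i for s in scales for i in s.item_ids]
    data = survey.dropna(subset=items)
    if data.empty:
        raise ValidationError("survey has no complete Likert responses")
    item_means = {i: float(data[i].mean()) for i in items}
    indicator_means = {
        s.scale_name: float(np.mean([item_means[i] for i in s.item_ids]))
        for s in scales
    }
    overall = overall_mean_from_indicators(
        indicator_means, {s.scale_name: len(s.item_ids) for s in scales}
    )
    walk = {}
    for i in items:
        col = walk_column(i)
        if col in survey.columns:
            walk[i] = distance_demand_item(survey[col])
    return DemandSummary(item_means, indicator_means, overall, walk)


def distance_demand_item(responses: pd.Series) -> tuple[float, float, float]:
    x = responses.dropna().astype(int)
    bad = x[~x.isin([1, 2, 3])]
    if not bad.empty:
        raise ValidationError(
            f"walking-time codes outside 1-3 at rows {list(bad.index[:10])}"
        )
    n = len(x)
    if n == 0:
        raise ValidationError("no walking-time responses")
    counts = x.value_counts()
    return tuple(float(counts.get(c, 0)) / n for c in (1, 2, 3))


def distance_demand(
    survey: pd.DataFrame,
    items: list[str] | None = None,
) -> dict[str, tuple[float, float, float]]:
    """Per-item proportions in the three walking-time categories."""
    if items is None:
        items = [c.removeprefix("walk_") for c in survey.columns
                 if c.startswith("walk_")]
    return {i: distance_demand_item(survey[walk_column(i)]) for i in items}


# ---------------------------------------------------------------------------
# housing price tiers

@dataclass(frozen=True)
class PriceClustering:
    assignments: np.ndarray  # tier label per input price
    centers: tuple[float, float, float]  # ascending RMB
    tier_labels: tuple[str, str, str]  # ('low', 'medium', 'high')
    boundaries: tuple[float, float]  # prices separating adjacent tiers


def cluster_prices(prices, k: int = 3, seed: int = 0,
                   n_init: int = 10) -> PriceClustering:
    """Tier housing prices with 1-D K-means and label tiers by center.

    Tier boundaries are midpoints between the highest member of one tier
    and the lowest member of the next.
    """
    x = np.asarray(prices, dtype=float)
    x = x[np.isfinite(x)]
    if k != 3:
        raise ValidationError("price tiering is defined for k = 3")
    if np.unique(x).size < k:
        raise ValidationError(
            f"need at least {k} distinct prices, got {np.unique(x).size}"
        )
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    raw = km.fit_predict(x.reshape(-1, 1))
    centers = km.cluster_centers_.ravel()
    order = np.argsort(centers)
    rank = np.empty_like(order)
    rank[order] = np.arange(k)
    tiers = np.array(["low", "medium", "high"])[rank[raw]]
    boundaries = []
    for lo, hi in ((0, 1), (1, 2)):
        upper_of_low = x[rank[raw] == lo].max()
        lower_of_high = x[rank[raw] == hi].min()
        boundaries.append(0.5 * (upper_of_low + lower_of_high))
    return PriceClustering(
        assignments=tiers,
        centers=tuple(np.sort(centers)),
        tier_labels=("low", "medium", "high"),
        boundaries=tuple(boundaries),
    )


# ---------------------------------------------------------------------------
# group comparison and regression

@dataclass(frozen=True)
class EffectReport:
    kind: str  # 'anova' or 'logistic'
    grouping: str  # grouping variable or outcome name
    table: pd.DataFrame


def group_anova(
    survey: pd.DataFrame,
    grouping: str,
    items: list[str] | None = None,
    alpha: float = 0.05,
    welch: bool = False,
) -> EffectReport:
    """Per-item one-way ANOVA of Likert scores across groups.

    Classic fixed-effects F by default; ``welch=True`` switches to the
    Welch-corrected variant.  Returns group means, F, p and a significance
    flag at ``alpha``.
    """
    if grouping not in survey.columns:
        raise ValidationError(f"grouping column {grouping!r} not in survey")
    if items is None:
        items = [i for s in DEFAULT_SCALES for i in s.item_ids]
    groups = survey[grouping].dropna().unique()
    if len(groups) < 2:
        raise ValidationError("ANOVA needs at least 2 groups")
    rows = []
    for item in items:
        samples, labels = [], []
        for g in sorted(groups, key=str):
            vals = survey.loc[survey[grouping] == g, item].dropna().to_numpy(float)
            if len(vals) < 2:
                raise ValidationError(
                    f"group {g!r} has fewer than 2 observations on {item!r}"
                )
            samples.append(vals)
            labels.append(g)
        if welch:
            stat, p = _welch_anova(samples)
        else:
            stat, p = stats.f_oneway(*samples)
        row = {"item": item, "F": float(stat), "p": float(p),
               "significant": bool(p < alpha)}
        for g, vals in zip(labels, samples):
            row[f"mean[{g}]"] = float(vals.mean())
        rows.append(row)
    return EffectReport(kind="anova", grouping=grouping, table=pd.DataFrame(rows))


def _welch_anova(samples: list[np.ndarray]) -> tuple[float, float]:
    k = len(samples)
    n = np.array([len(s) for s in samples], dtype=float)
    m = np.array([s.mean() for s in samples])
    v = np.array([s.var(ddof=1) for s in samples])
    w = n / v
    mw = (w * m).sum() / w.sum()
    num = ((w * (m - mw) ** 2).sum()) / (k - 1)
    tmp = ((1 - w / w.sum()) ** 2 / (n - 1)).sum() / (k**2 - 1)
    den = 1 + 2 * (k - 2) * tmp
    f = num / den
    df2 = 1.0 / (3 * tmp)
    return float(f), float(stats.f.sf(f, k - 1, df2))


def dichotomize_scale(
    survey: pd.DataFrame, scale: ScaleDefinition, threshold: float = 3.0
) -> pd.Series:
    """Binary demand indicator: 1 when the scale's mean item score >= threshold."""
    means = survey.loc[:, list(scale.item_ids)].mean(axis=1)
    return (means >= threshold).astype(int)


def attribute_logistic(
    survey: pd.DataFrame,
    outcome: str,
    attributes: list[str] = ("self_care", "income", "education"),
    threshold: float = 3.0,
) -> EffectReport:
    """Logistic regression of a binary demand outcome on ordinal attributes.

    ``outcome`` may name a binary column of the survey or a primary
    indicator, in which case the respondent's mean score on that indicator
    is dichotomized at ``threshold``.  Attributes enter as single numeric
    covariates in their ordinal coding.  Reports coefficient, standard
    error, Wald z, two-sided p and OR = exp(coefficient) per attribute.
    """
    byname = scales_by_name()
    if outcome in survey.columns:
        y = survey[outcome].astype(float)
    elif outcome in byname:
        y = dichotomize_scale(survey, byname[outcome], threshold).astype(float)
    else:
        raise ValidationError(
            f"outcome {outcome!r} is neither a survey column nor a known indicator"
        )
    uniq = set(np.unique(y.dropna()))
    if not uniq <= {0.0, 1.0} or len(uniq) < 2:
        raise ValidationError("outcome must be binary with both classes present")
    missing = [a for a in attributes if a not in survey.columns]
    if missing:
        raise ValidationError(f"attributes missing from survey: {missing}")
    X = sm.add_constant(survey.loc[:, list(attributes)].astype(float))
    mask = y.notna() & X.notna().all(axis=1)
    try:
        fit = sm.Logit(y[mask], X[mask]).fit(disp=0, maxiter=100)
    except Exception as exc:  # statsmodels raises several flavors here
        raise ComputationError(f"logistic fit failed: {exc}") from exc
    if not fit.mle_retvals.get("converged", True):
        raise ComputationError(
            "logistic fit did not converge (possible separation); "
            f"diagnostics: {fit.mle_retvals}"
        )
    if np.any(np.abs(fit.params.drop("const")) > 15):
        raise ComputationError(
            "implausibly large coefficient: complete or quasi-separation suspected"
        )
    rows = []
    for a in attributes:
        rows.append(
            {
                "attribute": a,
                "coef": float(fit.params[a]),
                "error": float(fit.bse[a]),
                "z": float(fit.tvalues[a]),
                "p": float(fit.pvalues[a]),
                "OR": float(np.exp(fit.params[a])),
            }
        )
    return EffectReport(kind="logistic", grouping=outcome, table=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# community aging

def aging_rates(communities: pd.DataFrame) -> pd.DataFrame:
    """Per-community aging rate = older population / total population."""
    required = {"community_id", "population", "older_population"}
    missing = required - set(communities.columns)
    if missing:
        raise ValidationError(f"communities table missing columns: {sorted(missing)}")
    if (communities["population"] <= 0).any():
        bad = communities.loc[communities["population"] <= 0, "community_id"]
        raise ValidationError(f"zero or negative population in: {list(bad)}")
    out = communities.loc[:, ["community_id", "population", "older_population"]].copy()
    out["aging_rate"] = out["older_population"] / out["population"]
    return out
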