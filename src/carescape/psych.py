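"""Reliability and validity statistics for the Likert demand battery.

Implements the four statistics the survey analysis relies on: Cronbach's
alpha (raw covariance form by default, standardized on request), corrected
item-total correlations, the Kaiser-Meyer-Olkin sampling-adequacy measure,
and Bartlett's test of sphericity.  All accept a respondents-by-items
matrix; rows with missing values are dropped listwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ComputationError, ValidationError
from .scales import ScaleDefinition


@dataclass(frozen=True)
class ScaleReport:
    scale_name: str
    alpha: float
    item_stats: dict[str, float]  # item id -> corrected item-total correlation
    kmo: float
    bartlett_chi2: float
    bartlett_df: int
    bartlett_p: float
    n: int

    def to_dict(self) -> dict:
        return {
            "scale_name": self.scale_name,
            "alpha": self.alpha,
            "item_stats": dict(self.item_stats),
            "kmo": self.kmo,
            "bartlett_chi2": self.bartlett_chi2,
            "bartlett_df": self.bartlett_df,
            "bartlett_p": self.bartlett_p,
            "n": self.n,
        }


def _as_matrix(item_matrix) -> np.ndarray:
    X = np.asarray(item_matrix, dtype=float)
    if X.ndim != 2:
        raise ValidationError("item matrix must be 2-D (respondents x items)")
    return X


def cronbach_alpha(item_matrix, standardized: bool = False) -> float:
    """Internal-consistency reliability of a multi-item scale.

    ``alpha = k/(k-1) * (1 - sum(var_i) / var(total))`` with n-1 sample
    variances.  With ``standardized=True`` items are z-scored first, which
    makes alpha a function of the mean inter-item correlation alone.
    """
    X = _as_matrix(item_matrix)
    n, k = X.shape
    if k < 2:
        raise ValidationError("alpha needs at least 2 items")
    if n < 3:
        raise ValidationError("alpha needs at least 3 respondents")
    if standardized:
        sd = X.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise ComputationError("zero-variance item: standardized alpha undefined")
        X = (X - X.mean(axis=0)) / sd
    item_var = X.var(axis=0, ddof=1)
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ComputationError("total score has zero variance: alpha undefined")
    return float(k / (k - 1) * (1.0 - item_var.sum() / total_var))


def corrected_item_total(item_matrix, item_index: int) -> float:
    """Pearson correlation of one item with the sum of the other items."""
    X = _as_matrix(item_matrix)
    if X.shape[1] < 3:
        raise ValidationError("corrected item-total needs at least 3 items")
    item = X[:, item_index]
    rest = np.delete(X, item_index, axis=1).sum(axis=1)
    if item.std(ddof=1) == 0 or rest.std(ddof=1) == 0:
        raise ComputationError("zero variance: item-total correlation undefined")
    return float(np.corrcoef(item, rest)[0, 1])


def kmo(item_matrix) -> float:
    """Kaiser-Meyer-Olkin measure of sampling adequacy.

    Compares squared simple correlations with squared partial correlations
    (off-diagonal elements of the scaled inverse correlation matrix):
    values near 1 mean the items share enough correlation for factoring.
    """
    X = _as_matrix(item_matrix)
    if X.shape[1] < 2:
        raise ValidationError("KMO needs at least 2 items")
    R = np.corrcoef(X, rowvar=False)
    try:
        Q = np.linalg.inv(R)
    except np.linalg.LinAlgError as exc:
        raise ComputationError(
            "correlation matrix is singular (collinear items); KMO undefined"
        ) from exc
    d = np.sqrt(np.outer(np.diag(Q), np.diag(Q)))
    partial = -Q / d
    off = ~np.eye(R.shape[0], dtype=bool)
    r2 = (R[off] ** 2).sum()
    p2 = (partial[off] ** 2).sum()
    return float(r2 / (r2 + p2))


def bartlett_sphericity(item_matrix) -> tuple[float, int, float]:
    """Bartlett's chi-square test that the correlation matrix is identity.

    ``chi2 = -(n - 1 - (2k + 5)/6) * ln det(R)`` on ``k(k-1)/2`` degrees of
    freedom, p from the upper tail.
    """
    X = _as_matrix(item_matrix)
    n, k = X.shape
    if n <= k:
        raise ValidationError("Bartlett test needs more respondents than items")
    R = np.corrcoef(X, rowvar=False)
    sign, logdet = np.linalg.slogdet(R)
    if sign <= 0:
        raise ComputationError(
            "correlation matrix is not positive definite; Bartlett test undefined"
        )
    chi2 = -(n - 1 - (2 * k + 5) / 6.0) * logdet
    df = k * (k - 1) // 2
    p = float(stats.chi2.sf(chi2, df))
    return float(chi2), int(df), p


def scale_report(survey: pd.DataFrame, scale: ScaleDefinition) -> ScaleReport:
    """Assemble alpha, item-total correlations, KMO and Bartlett for a scale.

    Rows with any missing item response are dropped listwise.
    """
    missing = [i for i in scale.item_ids if i not in survey.columns]
    if missing:
        raise ValidationError(
            f"scale {scale.scale_name!r}: items missing from survey: {missing}"
        )
    X = survey.loc[:, list(scale.item_ids)].dropna()
    if len(X) < 3:
        raise ValidationError(
            f"scale {scale.scale_name!r}: fewer than 3 complete responses"
        )
    M = X.to_numpy(dtype=float)
    chi2, df, p = bartlett_sphericity(M)
    item_stats = {
        item: corrected_item_total(M, idx)
        for idx, item in enumerate(scale.item_ids)
    }
    return ScaleReport(
        scale_name=scale.scale_name,
        alpha=cronbach_alpha(M),
        item_stats=item_stats,
        kmo=kmo(M),
        bartlett_chi2=chi2,
        bartlett_df=df,
        bartlett_p=p,
        n=len(X),
    )


def reliability_table(reports: list[ScaleReport]) -> pd.DataFrame:
    """Long-format table: one row per item with its scale's summary columns."""
    rows = []
    for rep in reports:
        for item, r in rep.item_stats.items():
            rows.append(
                {
                    "scale": rep.scale_name,
                    "item": item,
                    "corrected_item_total": round(r, 3),
                    "alpha": round(rep.alpha, 3),
                    "kmo": round(rep.kmo, 3),
                    "bartlett_chi2": round(rep.bartlett_chi2, 3),
                    "bartlett_df": rep.bartlett_df,
                    "bartlett_p": round(rep.bartlett_p, 4),
                    "n": rep.n,
                }
            )
    return pd.DataFrame(rows)
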