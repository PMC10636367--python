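"""Depression outcome variables and their association with connectivity.

Covers the subject-level correlations (baseline, week-8, SD of weekly
scores, held-out-item proxy SD), the control regressions, and the
node-valence analysis over enumerated subsets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import DegenerateDataError, outlier_pearson
from .enumeration import SubsetAssociation
from .model import Cohort
from .networks import NodeSubset

__all__ = [
    "compute_outcomes",
    "correlate",
    "regression_control",
    "valence_association",
    "RegressionControlResult",
    "OutcomeError",
]

WEEK8_INDEX = 8


class OutcomeError(ValueError):
    pass


def compute_outcomes(
    cohort: Cohort,
    holdout_item: str | None = None,
    pool_items: list[str] | None = None,
    include_baseline_in_sd: bool = True,
    min_scores_for_sd: int = 2,
) -> pd.DataFrame:
    """Per-participant outcome table.

    Columns: ``baseline``, ``week8`` (index-8 administration only, no
    carry-forward), ``sd_depression`` (sample SD over available scores,
    baseline included by default), ``proxy_sd`` (SD of the held-out EMA
    item, if requested) and ``mean_item_variance`` (mean within-person
    variance over pool items, holdout excluded).

    Raises
    ------
    OutcomeError
        If the holdout item is part of the enumeration pool (circularity).
    """
    if holdout_item is not None and pool_items is not None:
        if holdout_item in pool_items:
            raise OutcomeError(
                f"holdout item {holdout_item!r} is inside the enumeration pool"
            )
    rows = []
    for pid, panel in cohort.panels.items():
        series = cohort.depression.get(pid)
        baseline = week8 = sd_dep = np.nan
        if series is not None:
            baseline = series.baseline
            week8 = series.week(WEEK8_INDEX)
            scores = series.scores if include_baseline_in_sd else series.scores[1:]
            scores = scores[np.isfinite(scores)]
            if scores.size >= min_scores_for_sd:
                sd_dep = float(scores.std(ddof=1))
        proxy = np.nan
        if holdout_item is not None:
            col = panel.values[:, panel.item_index(holdout_item)]
            obs = col[np.isfinite(col)]
            if obs.size >= 2:
                proxy = float(obs.std(ddof=1))
        items = pool_items if pool_items is not None else panel.item_names
        variances = []
        for item in items:
            if item == holdout_item:
                continue
            col = panel.values[:, panel.item_index(item)]
            obs = col[np.isfinite(col)]
            if obs.size >= 2:
                variances.append(obs.var(ddof=1))
        mean_var = float(np.mean(variances)) if variances else np.nan
        rows.append(
            {
                "participant": pid,
                "baseline": baseline,
                "week8": week8,
                "sd_depression": sd_dep,
                "proxy_sd": proxy,
                "mean_item_variance": mean_var,
            }
        )
    return pd.DataFrame(rows).set_index("participant")


def correlate(x, y, outlier_sd: float = 3.0) -> tuple[float, float, int]:
    """Subject-level Pearson association with joint 3-SD outlier removal.

    ``x`` and ``y`` may be aligned arrays or participant-keyed dicts /
    Series.  Returns ``(r, p, n_used)``.
    """
    x, y = _align(x, y)
    try:
        return outlier_pearson(x, y, outlier_sd)
    except DegenerateDataError as exc:
        raise OutcomeError(str(exc)) from exc


def _align(x, y) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(x, dict):
        x = pd.Series(x)
    if isinstance(y, dict):
        y = pd.Series(y)
    if isinstance(x, pd.Series) and isinstance(y, pd.Series):
        common = x.index.intersection(y.index)
        return x.loc[common].to_numpy(float), y.loc[common].to_numpy(float)
    return np.asarray(x, float), np.asarray(y, float)


@dataclass
class RegressionControlResult:
    """Standardized OLS with per-predictor inference."""

    model: str
    coefficients: pd.DataFrame  # index = predictor; beta, se, t, p
    n: int

    def beta(self, name: str) -> float:
        return float(self.coefficients.loc[name, "beta"])

    def p(self, name: str) -> float:
        return float(self.coefficients.loc[name, "p"])


def regression_control(
    dv, ivs: dict[str, object], condition_limit: float = 1e8
) -> RegressionControlResult:
    """OLS of a z-scored DV on z-scored IVs with intercept.

    Because every variable is standardized, a single-IV model's
    coefficient equals the Pearson correlation, so control results read on
    the familiar r scale.  Complete cases only.
    """
    names = list(ivs)
    frames = {"__dv__": _as_series(dv)}
    frames.update({k: _as_series(v) for k, v in ivs.items()})
    df = pd.DataFrame(frames).dropna()
    n = len(df)
    if n < len(names) + 3:
        raise OutcomeError(f"need >= {len(names) + 3} complete cases, got {n}")

    def z(v):
        sd = v.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            raise OutcomeError("zero-variance variable in regression")
        return (v - v.mean()) / sd

    yz = z(df["__dv__"].to_numpy())
    Xz = np.column_stack([z(df[k].to_numpy()) for k in names])
    X = np.column_stack([np.ones(n), Xz])
    if np.linalg.cond(X) > condition_limit:
        raise OutcomeError("collinear independent variables")
    beta, *_ = np.linalg.lstsq(X, yz, rcond=None)
    resid = yz - X @ beta
    dof = n - X.shape[1]
    sigma2 = resid @ resid / dof
    cov = sigma2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    t = beta / se
    p = 2 * stats.t.sf(np.abs(t), dof)
    table = pd.DataFrame(
        {"beta": beta[1:], "se": se[1:], "t": t[1:], "p": p[1:]}, index=names
    )
    return RegressionControlResult(
        model=f"z(dv) ~ {' + '.join('z(' + k + ')' for k in names)}",
        coefficients=table,
        n=n,
    )


def _as_series(v) -> pd.Series:
    if isinstance(v, pd.Series):
        return v.astype(float)
    if isinstance(v, dict):
        return pd.Series(v, dtype=float)
    return pd.Series(np.asarray(v, dtype=float))


def valence_association(
    subsets: list[NodeSubset], associations: SubsetAssociation
) -> tuple[float, float]:
    """Correlation between a subset's negative-item count and its
    connectivity-outcome r, across all enumerated subsets."""
    n_negative = np.array([s.n_negative for s in subsets], dtype=float)
    r_values = np.asarray(associations.r, dtype=float)
    if n_negative.size != r_values.size:
        raise OutcomeError("subsets and associations are not aligned")
    ok = np.isfinite(r_values)
    n_negative, r_values = n_negative[ok], r_values[ok]
    if np.unique(n_negative).size < 2:
        raise OutcomeError("degenerate valence distribution")
    if np.unique(r_values).size < 2:
        raise OutcomeError("degenerate association values")
    r, p = stats.pearsonr(n_negative, r_values)
    return float(r), float(p)
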