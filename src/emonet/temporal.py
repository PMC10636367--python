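"""Weekly connectivity and its lagged relation to weekly depression.

Weekly contemporaneous networks are derived from the full-series VAR
residuals partitioned by week (a per-week VAR refit would be hopelessly
underpowered at ~14 assessments per week).  The lagged model is a pooled
regression with person-specific intercepts: depression at week w+1 on
connectivity at week w ("before") or depression at week w-1 on
connectivity at week w ("after").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .model import Cohort, DepressionSeries
from .networks import (
    FitError,
    MIN_EXTRA_ROWS,
    NodeSubset,
    ResidualRecord,
    contemporaneous_from_residuals,
    fit_var,
)

__all__ = ["weekly_connectivity", "lagged_model", "LaggedModelResult", "TemporalError"]


class TemporalError(ValueError):
    pass


@dataclass
class LaggedModelResult:
    direction: str  # 'before' or 'after'
    beta: float
    se: float
    t: float
    p: float
    n_observations: int
    n_participants: int


def _weekly_slices(record: ResidualRecord, per_week: int, n_weeks: int):
    """Restrict a residual record to each week's grid slots."""
    for w in range(1, n_weeks + 1):
        t_lo, t_hi = (w - 1) * per_week, w * per_week
        sub = ResidualRecord(items=record.items)
        ok = True
        for rows, resid in zip(record.rows, record.residuals):
            inside = (rows >= t_lo) & (rows < t_hi)
            if inside.sum() < len(record.items) + MIN_EXTRA_ROWS:
                ok = False
                break
            sub.rows.append(rows[inside])
            sub.residuals.append(resid[inside])
        yield w, (sub if ok else None)


def weekly_connectivity(
    cohort: Cohort,
    subsets: list[NodeSubset],
    per_week: int = 14,
    n_weeks: int = 8,
    mode: str = "partial",
) -> pd.DataFrame:
    """Participant x week table of mean contemporaneous connectivity.

    For every subset the full-series VAR is fit once; its residuals are
    split by week and a contemporaneous network is computed from each
    week's rows (weeks with fewer than k + 2 usable rows are missing for
    that subset).  Weekly values are averaged over subsets with data.
    """
    weeks = list(range(1, n_weeks + 1))
    out = pd.DataFrame(np.nan, index=list(cohort.panels), columns=weeks)
    for pid, panel in cohort.panels.items():
        sums = np.zeros(n_weeks)
        counts = np.zeros(n_weeks, dtype=int)
        for sub in subsets:
            try:
                _, record = fit_var(panel, sub)
            except FitError:
                continue
            for w, weekly_rec in _weekly_slices(record, per_week, n_weeks):
                if weekly_rec is None:
                    continue
                try:
                    net = contemporaneous_from_residuals(weekly_rec, mode=mode)
                except FitError:
                    continue
                sums[w - 1] += net.connectivity
                counts[w - 1] += 1
        with np.errstate(invalid="ignore"):
            vals = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        out.loc[pid] = vals
    return out


def lagged_model(
    weekly: pd.DataFrame,
    depression: dict[str, DepressionSeries],
    direction: str = "before",
    min_participants: int = 10,
    min_pairs_per_participant: int = 2,
) -> LaggedModelResult:
    """Pooled regression of weekly depression on lagged weekly connectivity.

    ``before``: depression at week w+1 ~ connectivity at week w.
    ``after``:  depression at week w-1 ~ connectivity at week w.
    Both variables are z-scored over the pooled sample; the predictor is
    person-mean centered and person intercept dummies absorb stable
    between-person differences, so the coefficient reflects within-person
    temporal coupling.
    """
    if direction not in ("before", "after"):
        raise TemporalError(f"unknown direction {direction!r}")
    offset = 1 if direction == "before" else -1

    rows = []
    for pid in weekly.index:
        series = depression.get(pid)
        if series is None:
            continue
        for w in weekly.columns:
            conn = weekly.loc[pid, w]
            target_week = w + offset
            if target_week < 0 or target_week >= series.scores.size:
                continue
            dep = series.scores[target_week]
            if np.isfinite(conn) and np.isfinite(dep):
                rows.append((pid, float(conn), float(dep)))
    df = pd.DataFrame(rows, columns=["pid", "conn", "dep"])
    counts = df.groupby("pid").size()
    usable = counts[counts >= min_pairs_per_participant].index
    df = df[df["pid"].isin(usable)]
    n_part = df["pid"].nunique()
    if n_part < min_participants:
        raise TemporalError(
            f"need >= {min_participants} participants with "
            f">= {min_pairs_per_participant} week pairs, got {n_part}"
        )
    n = len(df)
    if df["conn"].std(ddof=1) == 0 or df["dep"].std(ddof=1) == 0:
        raise TemporalError("degenerate predictor or outcome variance")

    conn_z = (df["conn"] - df["conn"].mean()) / df["conn"].std(ddof=1)
    dep_z = (df["dep"] - df["dep"].mean()) / df["dep"].std(ddof=1)
    conn_c = conn_z - conn_z.groupby(df["pid"]).transform("mean")
    if conn_c.std(ddof=1) == 0:
        raise TemporalError("no within-person predictor variance")

    dummies = pd.get_dummies(df["pid"], dtype=float).to_numpy()
    X = np.column_stack([conn_c.to_numpy(), dummies])
    y = dep_z.to_numpy()
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = n - X.shape[1]
    if dof < 1:
        raise TemporalError("not enough observations for inference")
    sigma2 = resid @ resid / dof
    XtX_inv = np.linalg.pinv(X.T @ X)
    se = float(np.sqrt(sigma2 * XtX_inv[0, 0]))
    t = float(beta[0] / se)
    p = float(2 * stats.t.sf(abs(t), dof))
    return LaggedModelResult(
        direction=direction,
        beta=float(beta[0]),
        se=se,
        t=t,
        p=p,
        n_observations=n,
        n_participants=int(n_part),
    )
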