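"""Inclusion filtering and per-item series preparation.

Inclusion mirrors the study rules: a participant must have completed at
least 75% of scheduled assessments (an assessment counts as completed if
at least one item was answered) and at least 7 of the 9 depression
questionnaires.  Both thresholds are configurable.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .model import Cohort, EmaPanel

__all__ = ["apply_inclusion", "prepare_series", "PreparationError"]


class PreparationError(ValueError):
    pass


def apply_inclusion(
    cohort: Cohort,
    min_completion: float = 0.75,
    min_weekly: int = 7,
) -> tuple[Cohort, pd.DataFrame]:
    """Filter a cohort by completion and weekly-questionnaire thresholds.

    Returns the filtered cohort and a per-participant report with columns
    ``completion, n_weekly_scores, included, exclusion_reason``.  If the
    cohort carries no depression data at all, the weekly criterion is
    skipped (panels-only workflows).  Filtering is idempotent.
    """
    if cohort.n_participants == 0:
        raise PreparationError("cohort is empty")
    check_weekly = len(cohort.depression) > 0
    rows = []
    keep = []
    for pid, panel in cohort.panels.items():
        completed = panel.observed_mask.any(axis=1).sum()
        completion = completed / panel.n_assessments
        series = cohort.depression.get(pid)
        n_weekly = series.n_scores if series is not None else 0
        reason = None
        if completion < min_completion:
            reason = "completion"
        elif check_weekly and n_weekly < min_weekly:
            reason = "weekly"
        included = reason is None
        if included:
            keep.append(pid)
        rows.append(
            {
                "participant": pid,
                "completion": completion,
                "n_weekly_scores": n_weekly if check_weekly else np.nan,
                "included": included,
                "exclusion_reason": reason,
            }
        )
    report = pd.DataFrame(rows).set_index("participant")
    return cohort.subset(keep), report


def prepare_series(
    panel: EmaPanel, detrend: bool = False, standardize: bool = True
) -> EmaPanel:
    """Optionally detrend and/or z-score each item within participant.

    Trends are ordinary linear fits on observed points only; z-scoring
    uses the observed mean and sample SD.  Missing cells stay missing.
    With both flags off, the panel is returned unchanged (same object).
    """
    if not detrend and not standardize:
        return panel
    values = panel.values.copy()
    t = np.arange(panel.n_assessments, dtype=float)
    for j, item in enumerate(panel.item_names):
        col = values[:, j]
        obs = np.isfinite(col)
        n_obs = int(obs.sum())
        if detrend:
            if n_obs < 3:
                raise PreparationError(
                    f"item {item!r}: {n_obs} observed points, need >= 3 to detrend"
                )
            slope, icept = np.polyfit(t[obs], col[obs], 1)
            col = col - (icept + slope * t)
        if standardize:
            sd = np.nanstd(col, ddof=1) if n_obs > 1 else 0.0
            if not np.isfinite(sd) or sd == 0:
                raise PreparationError(
                    f"item {item!r} has zero variance, cannot standardize"
                )
            col = (col - np.nanmean(col)) / sd
        values[:, j] = col
    return EmaPanel(
        participant_id=panel.participant_id,
        item_names=list(panel.item_names),
        item_valence=dict(panel.item_valence),
        values=values,
        scale="continuous",
        spacing_hours=panel.spacing_hours,
    )
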