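"""Core data containers for EMA panels, depression series and cohorts.

Missing values are represented by ``numpy.nan`` everywhere; assessment
alignment is by integer slot index on a fixed nominal spacing, never by
wall-clock time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EmaPanel",
    "DepressionSeries",
    "Cohort",
    "SCALE_BOUNDS",
    "VALENCES",
    "PanelError",
]

#: Inclusive bounds of each supported response scale.  ``continuous`` is the
#: unbounded scale produced by simulation in continuous mode and by
#: within-person standardization.
SCALE_BOUNDS: dict[str, tuple[float, float]] = {
    "likert": (-3.0, 3.0),
    "vas": (0.0, 100.0),
    "continuous": (-math.inf, math.inf),
}

VALENCES = ("negative", "positive")

MAX_DEPRESSION_SCORES = 9  # baseline + 8 weekly administrations
DEPRESSION_BOUNDS = (0.0, 60.0)


class PanelError(ValueError):
    """Raised when a container violates its structural invariants."""


@dataclass
class EmaPanel:
    """One participant's item ratings over an equidistant assessment grid.

    Parameters
    ----------
    participant_id
        Opaque identifier.
    item_names
        Ordered, unique item labels; columns of ``values``.
    item_valence
        Mapping of every item to ``"negative"`` or ``"positive"``.
    values
        ``(T, n_items)`` float array; missing cells are NaN.  Missed
        assessments are present as all-NaN rows, never deleted.
    scale
        One of :data:`SCALE_BOUNDS`; every observed value must lie inside
        the declared bounds.
    spacing_hours
        Nominal spacing between consecutive grid slots.
    """

    participant_id: str
    item_names: list[str]
    item_valence: dict[str, str]
    values: np.ndarray
    scale: str = "likert"
    spacing_hours: float = 12.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise PanelError("values must be a 2-D (T, n_items) array")
        self.item_names = list(self.item_names)
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        if len(set(self.item_names)) != len(self.item_names):
            raise PanelError("item names must be unique")
        if self.values.shape[1] != len(self.item_names):
            raise PanelError(
                f"values has {self.values.shape[1]} columns but "
                f"{len(self.item_names)} item names"
            )
        missing_valence = [i for i in self.item_names if i not in self.item_valence]
        if missing_valence:
            raise PanelError(f"no valence declared for items: {missing_valence}")
        bad_valence = {
            i: v
            for i, v in self.item_valence.items()
            if i in self.item_names and v not in VALENCES
        }
        if bad_valence:
            raise PanelError(f"invalid valence labels: {bad_valence}")
        if self.scale not in SCALE_BOUNDS:
            raise PanelError(f"unknown scale {self.scale!r}")
        lo, hi = SCALE_BOUNDS[self.scale]
        obs = self.values[np.isfinite(self.values)]
        if obs.size and (obs.min() < lo or obs.max() > hi):
            raise PanelError(
                f"observed values outside {self.scale} bounds [{lo}, {hi}] "
                f"for participant {self.participant_id}"
            )

    # -- views ------------------------------------------------------------
    @property
    def n_items(self) -> int:
        return len(self.item_names)

    @property
    def n_assessments(self) -> int:
        return self.values.shape[0]

    @property
    def grid(self) -> np.ndarray:
        """Assessment slot indices 0..T-1 (equidistant by construction)."""
        return np.arange(self.n_assessments)

    @property
    def observed_mask(self) -> np.ndarray:
        return np.isfinite(self.values)

    def item_index(self, item: str) -> int:
        try:
            return self.item_names.index(item)
        except ValueError:
            raise KeyError(
                f"item {item!r} not in panel of participant {self.participant_id}"
            ) from None

    def negative_items(self) -> list[str]:
        return [i for i in self.item_names if self.item_valence[i] == "negative"]

    def copy(self) -> "EmaPanel":
        return EmaPanel(
            participant_id=self.participant_id,
            item_names=list(self.item_names),
            item_valence=dict(self.item_valence),
            values=self.values.copy(),
            scale=self.scale,
            spacing_hours=self.spacing_hours,
        )


@dataclass
class DepressionSeries:
    """Baseline plus weekly depression sum scores for one participant.

    ``scores[0]`` is the baseline administration; indices 1..8 are weekly
    follow-ups.  Missing administrations are NaN; at most 9 entries.
    """

    participant_id: str
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 1:
            raise PanelError("scores must be 1-D")
        if self.scores.size > MAX_DEPRESSION_SCORES:
            raise PanelError(
                f"at most {MAX_DEPRESSION_SCORES} depression scores allowed, "
                f"got {self.scores.size}"
            )
        lo, hi = DEPRESSION_BOUNDS
        obs = self.scores[np.isfinite(self.scores)]
        if obs.size and (obs.min() < lo or obs.max() > hi):
            raise PanelError(
                f"depression scores outside [{lo:g}, {hi:g}] for "
                f"participant {self.participant_id}"
            )

    @property
    def n_scores(self) -> int:
        """Number of non-missing administrations (baseline included)."""
        return int(np.isfinite(self.scores).sum())

    @property
    def baseline(self) -> float:
        return float(self.scores[0]) if self.scores.size else math.nan

    def week(self, w: int) -> float:
        """Score of weekly administration ``w`` (0 = baseline); NaN if absent."""
        if w < 0 or w >= MAX_DEPRESSION_SCORES:
            raise IndexError(f"week index {w} outside 0..8")
        return float(self.scores[w]) if w < self.scores.size else math.nan


@dataclass
class Cohort:
    """Panels and depression series keyed by participant id."""

    panels: dict[str, EmaPanel] = field(default_factory=dict)
    depression: dict[str, DepressionSeries] = field(default_factory=dict)
    design_label: str = ""

    @property
    def participants(self) -> list[str]:
        return list(self.panels)

    @property
    def n_participants(self) -> int:
        return len(self.panels)

    def validate_matched(self) -> None:
        """Check the post-inclusion invariant: panels and depression match."""
        if set(self.panels) != set(self.depression):
            only_p = set(self.panels) - set(self.depression)
            only_d = set(self.depression) - set(self.panels)
            raise PanelError(
                f"unmatched participants: panels-only={sorted(only_p)}, "
                f"depression-only={sorted(only_d)}"
            )

    def subset(self, participant_ids) -> "Cohort":
        ids = list(participant_ids)
        return Cohort(
            panels={p: self.panels[p] for p in ids if p in self.panels},
            depression={p: self.depression[p] for p in ids if p in self.depression},
            design_label=self.design_label,
        )
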