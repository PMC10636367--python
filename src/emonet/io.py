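"""Reading and writing the canonical on-disk formats.

EMA ratings and depression scores travel as long-format CSV; analysis
results are serialized as JSON (Python ``repr`` floats, so numeric
round-trips are exact to full double precision).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .model import (
    SCALE_BOUNDS,
    Cohort,
    DepressionSeries,
    EmaPanel,
    MAX_DEPRESSION_SCORES,
    DEPRESSION_BOUNDS,
)

__all__ = [
    "read_ema_table",
    "read_depression_table",
    "write_results",
    "read_results",
    "write_ema_table",
    "write_depression_table",
    "TableFormatError",
]

EMA_COLUMNS = ["participant", "assessment_index", "item", "value"]
DEPRESSION_COLUMNS = ["participant", "week", "score"]


class TableFormatError(ValueError):
    """Malformed input table (missing columns, bad values, duplicates)."""


def read_ema_table(
    path,
    scale: str,
    valence_map: dict[str, str],
    spacing_hours: float = 12.0,
) -> Cohort:
    """Read a long-format EMA CSV into a cohort of panels.

    Expects columns ``participant, assessment_index, item, value``.  Each
    participant gets a complete equidistant grid spanning their min..max
    assessment index; absent cells become NaN.

    Raises
    ------
    TableFormatError
        On unknown item labels, out-of-scale values, or duplicate
        (participant, index, item) rows.
    """
    if scale not in SCALE_BOUNDS:
        raise TableFormatError(f"unknown scale {scale!r}")
    df = pd.read_csv(path)
    missing_cols = [c for c in EMA_COLUMNS if c not in df.columns]
    if missing_cols:
        raise TableFormatError(f"missing columns {missing_cols} in {path}")

    unknown = sorted(set(df["item"].astype(str)) - set(valence_map))
    if unknown:
        raise TableFormatError(f"items not in valence map: {unknown}")

    lo, hi = SCALE_BOUNDS[scale]
    vals = pd.to_numeric(df["value"], errors="coerce")
    observed = vals.notna() & df["value"].notna()
    bad = observed & ((vals < lo) | (vals > hi))
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise TableFormatError(
            f"value {df['value'].iloc[row]!r} outside {scale} bounds "
            f"[{lo:g}, {hi:g}] at data row {row}"
        )

    dupes = df.duplicated(subset=["participant", "assessment_index", "item"])
    if dupes.any():
        first = df.loc[dupes].iloc[0]
        raise TableFormatError(
            "duplicate cell for participant "
            f"{first['participant']!r}, index {first['assessment_index']}, "
            f"item {first['item']!r}"
        )

    df = df.assign(value=vals)
    item_names = [i for i in valence_map if i in set(df["item"].astype(str))]
    panels: dict[str, EmaPanel] = {}
    for pid, grp in df.groupby("participant", sort=True):
        idx = grp["assessment_index"].astype(int)
        t0, t1 = int(idx.min()), int(idx.max())
        grid_len = t1 - t0 + 1
        wide = np.full((grid_len, len(item_names)), np.nan)
        col_of = {name: j for j, name in enumerate(item_names)}
        rows = idx.to_numpy() - t0
        cols = grp["item"].astype(str).map(col_of).to_numpy()
        wide[rows, cols] = grp["value"].to_numpy()
        panels[str(pid)] = EmaPanel(
            participant_id=str(pid),
            item_names=item_names,
            item_valence={k: valence_map[k] for k in item_names},
            values=wide,
            scale=scale,
            spacing_hours=spacing_hours,
        )
    return Cohort(panels=panels)


def read_depression_table(path) -> dict[str, DepressionSeries]:
    """Read a ``participant, week, score`` CSV into depression series.

    Week 0 is baseline; weeks absent from the table stay NaN.
    """
    df = pd.read_csv(path)
    missing_cols = [c for c in DEPRESSION_COLUMNS if c not in df.columns]
    if missing_cols:
        raise TableFormatError(f"missing columns {missing_cols} in {path}")
    weeks = df["week"].astype(int)
    if (weeks < 0).any() or (weeks >= MAX_DEPRESSION_SCORES).any():
        bad = weeks[(weeks < 0) | (weeks >= MAX_DEPRESSION_SCORES)].iloc[0]
        raise TableFormatError(f"week {bad} outside 0..{MAX_DEPRESSION_SCORES - 1}")
    scores = pd.to_numeric(df["score"], errors="coerce")
    lo, hi = DEPRESSION_BOUNDS
    bad_score = scores.notna() & ((scores < lo) | (scores > hi))
    if bad_score.any():
        raise TableFormatError(
            f"score {scores[bad_score].iloc[0]:g} outside [{lo:g}, {hi:g}]"
        )
    if df.duplicated(subset=["participant", "week"]).any():
        raise TableFormatError("duplicate (participant, week) rows")

    out: dict[str, DepressionSeries] = {}
    for pid, grp in df.groupby("participant", sort=True):
        series = np.full(MAX_DEPRESSION_SCORES, np.nan)
        series[grp["week"].astype(int).to_numpy()] = pd.to_numeric(
            grp["score"]
        ).to_numpy()
        out[str(pid)] = DepressionSeries(participant_id=str(pid), scores=series)
    return out


# -- writers ---------------------------------------------------------------


def write_ema_table(path, cohort: Cohort) -> None:
    """Write panels back to canonical long format (observed cells only)."""
    records = []
    for pid, panel in cohort.panels.items():
        t_idx, i_idx = np.nonzero(panel.observed_mask)
        for t, i in zip(t_idx, i_idx):
            records.append(
                (pid, int(t), panel.item_names[i], panel.values[t, i])
            )
    pd.DataFrame(records, columns=EMA_COLUMNS).to_csv(path, index=False)


def write_depression_table(path, depression: dict[str, DepressionSeries]) -> None:
    records = []
    for pid, series in depression.items():
        for w, score in enumerate(series.scores):
            if np.isfinite(score):
                records.append((pid, w, score))
    pd.DataFrame(records, columns=DEPRESSION_COLUMNS).to_csv(path, index=False)


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {
            "__type__": type(obj).__name__,
            **{
                f.name: _jsonable(getattr(obj, f.name))
                for f in dataclasses.fields(obj)
            },
        }
    if isinstance(obj, np.ndarray):
        return {"__ndarray__": obj.tolist(), "shape": list(obj.shape)}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, pd.DataFrame):
        return {
            "__dataframe__": {c: _jsonable(obj[c].to_numpy()) for c in obj.columns},
            "index": [str(i) for i in obj.index],
            "columns": [str(c) for c in obj.columns],
        }
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if obj is None or isinstance(obj, (str, bool, int, float)):
        return obj
    raise TypeError(f"cannot serialize object of type {type(obj).__name__}")


def write_results(path, payload) -> None:
    """Serialize any pipeline result to JSON.

    Floats are written with Python's shortest-repr, which round-trips to
    the exact same double, so numeric precision is preserved in full.
    NaN/Inf are emitted in JavaScript style (``NaN``), matching the reader.
    """
    path = Path(path)
    try:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(_jsonable(payload), fh, indent=1)
            fh.write("\n")
    except OSError as exc:
        raise OSError(f"cannot write results to {path}: {exc}") from exc


def read_results(path):
    """Load a :func:`write_results` file; ndarray markers become arrays."""

    def hook(d):
        if "__ndarray__" in d:
            return np.array(d["__ndarray__"], dtype=float).reshape(d["shape"])
        return d

    with open(path, encoding="utf-8") as fh:
        return json.load(fh, object_hook=hook)
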