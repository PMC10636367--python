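"""Case-dropping bootstrap stability and cross-sample comparison.

CS(0.7) is the largest fraction of cases (participants, or assessment
slots within every participant) that can be dropped while the re-estimated
exemplar network still correlates >= 0.7 with the full-data network in at
least 95% of bootstrap replicates (implemented as the 5th-percentile
rule).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .model import Cohort
from .networks import (
    FitError,
    NodeSubset,
    contemporaneous_from_residuals,
    fit_var,
)

__all__ = [
    "exemplar_network",
    "correlation_stability",
    "cross_sample_edge_correlation",
    "StabilityResult",
    "DEFAULT_DROP_GRID",
]

DEFAULT_DROP_GRID = tuple(np.round(np.arange(0.05, 0.76, 0.05), 2))


@dataclass
class StabilityResult:
    drop_grid: tuple[float, ...]
    percentile5: np.ndarray
    n_discarded: np.ndarray
    unreliable: np.ndarray
    cs: float
    cs_threshold: float
    B: int
    drop_unit: str
    network_type: str


def _participant_edges(
    cohort: Cohort, subset: NodeSubset, network_type: str, mode: str
) -> dict[str, np.ndarray]:
    """Per-participant edge matrix for every participant whose fit succeeds."""
    out: dict[str, np.ndarray] = {}
    for pid, panel in cohort.panels.items():
        try:
            directed, record = fit_var(panel, subset)
            if network_type == "directed":
                out[pid] = directed.edges
            else:
                out[pid] = contemporaneous_from_residuals(record, mode=mode).edges
        except FitError:
            continue
    return out


def _vectorize(edges: np.ndarray, network_type: str) -> np.ndarray:
    """Non-redundant edge vector: all k^2 entries for directed networks,
    unique off-diagonal entries for contemporaneous ones."""
    if network_type == "directed":
        return edges.ravel()
    iu = np.triu_indices(edges.shape[0], 1)
    return edges[iu]


def exemplar_network(
    cohort: Cohort,
    subset: NodeSubset,
    network_type: str = "contemporaneous",
    mode: str = "partial",
) -> np.ndarray:
    """Entrywise mean edge matrix across participants with successful fits."""
    per = _participant_edges(cohort, subset, network_type, mode)
    if not per:
        raise FitError("no participant produced a successful fit")
    return np.mean(list(per.values()), axis=0)


def cross_sample_edge_correlation(
    netA: np.ndarray, netB: np.ndarray, network_type: str
) -> float:
    """Pearson correlation of two exemplar networks' edge vectors."""
    a = _vectorize(np.asarray(netA, float), network_type)
    b = _vectorize(np.asarray(netB, float), network_type)
    if a.shape != b.shape:
        raise ValueError("networks have different shapes")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero variance in an edge vector")
    return float(stats.pearsonr(a, b)[0])


def correlation_stability(
    cohort: Cohort,
    subset: NodeSubset,
    network_type: str = "contemporaneous",
    drop_unit: str = "participants",
    B: int = 500,
    cs_threshold: float = 0.7,
    seed: int = 0,
    drop_grid: tuple[float, ...] = DEFAULT_DROP_GRID,
    mode: str = "partial",
) -> StabilityResult:
    """Case-dropping bootstrap of the exemplar network.

    For each drop fraction f, B replicates each remove a random fraction f
    of the chosen unit, re-estimate the exemplar network and correlate its
    edge vector with the full-data one; the 5th percentile of those
    correlations is recorded.  CS is the largest f on the grid such that
    every fraction up to and including f keeps the 5th percentile >=
    ``cs_threshold`` (0 if even the smallest fraction fails).

    Replicates whose data cannot be fit are discarded and counted; a
    fraction where more than half the replicates are discarded is marked
    unreliable.
    """
    if drop_unit not in ("participants", "assessments"):
        raise ValueError(f"unknown drop_unit {drop_unit!r}")
    rng = np.random.default_rng(seed)
    grid = tuple(drop_grid)
    if any(f < 0 or f >= 1 for f in grid):
        raise ValueError("drop fractions must lie in [0, 1)")

    full_per = _participant_edges(cohort, subset, network_type, mode)
    if not full_per:
        raise FitError("no successful full-data fits")
    full_vec = _vectorize(np.mean(list(full_per.values()), axis=0), network_type)
    pids = list(cohort.panels)
    n = len(pids)

    pct5 = np.full(len(grid), np.nan)
    n_discarded = np.zeros(len(grid), dtype=int)
    unreliable = np.zeros(len(grid), dtype=bool)

    for gi, f in enumerate(grid):
        corrs = []
        for _ in range(B):
            try:
                if drop_unit == "participants":
                    n_keep = max(1, int(round((1 - f) * n)))
                    kept = rng.choice(n, size=n_keep, replace=False)
                    mats = [
                        full_per[pids[i]] for i in kept if pids[i] in full_per
                    ]
                    if len(mats) < 1:
                        raise FitError("no fits in replicate")
                    rep_vec = _vectorize(np.mean(mats, axis=0), network_type)
                else:
                    mats = []
                    for pid in pids:
                        panel = cohort.panels[pid].copy()
                        T = panel.n_assessments
                        n_drop = int(round(f * T))
                        if n_drop:
                            dropped = rng.choice(T, size=n_drop, replace=False)
                            panel.values[dropped, :] = np.nan
                        try:
                            directed, record = fit_var(panel, subset)
                            mats.append(
                                directed.edges
                                if network_type == "directed"
                                else contemporaneous_from_residuals(
                                    record, mode=mode
                                ).edges
                            )
                        except FitError:
                            continue
                    if len(mats) < 1:
                        raise FitError("no fits in replicate")
                    rep_vec = _vectorize(np.mean(mats, axis=0), network_type)
                sd = rep_vec.std()
                if sd == 0 or full_vec.std() == 0:
                    raise FitError("degenerate replicate edge vector")
                corrs.append(float(stats.pearsonr(rep_vec, full_vec)[0]))
            except FitError:
                n_discarded[gi] += 1
        if n_discarded[gi] > B / 2:
            unreliable[gi] = True
        if corrs:
            pct5[gi] = float(np.percentile(corrs, 5))

    cs = 0.0
    order = np.argsort(grid)
    for gi in order:
        if np.isfinite(pct5[gi]) and pct5[gi] >= cs_threshold and not unreliable[gi]:
            cs = float(grid[gi])
        else:
            break
    return StabilityResult(
        drop_grid=grid,
        percentile5=pct5,
        n_discarded=n_discarded,
        unreliable=unreliable,
        cs=cs,
        cs_threshold=cs_threshold,
        B=B,
        drop_unit=drop_unit,
        network_type=network_type,
    )
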