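"""Exhaustive k-node subnetwork enumeration and cross-participant summaries.

A 16-item pool yields C(16, 5) = 4,368 candidate 5-node networks; every
participant's connectivity is computed in every one of them, then each
subnetwork's connectivity is correlated with an outcome across
participants (with per-analysis 3-SD outlier removal).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from ._stats import DegenerateDataError, outlier_pearson
from .model import Cohort
from .networks import (
    FitError,
    NodeSubset,
    connectivity,
    contemporaneous_from_residuals,
    fit_var,
)

__all__ = [
    "enumerate_subsets",
    "connectivity_matrix",
    "per_participant_mean",
    "subset_outcome_associations",
    "ConnectivityMatrixResult",
    "SubsetAssociation",
]


@dataclass
class ConnectivityMatrixResult:
    """participants x subsets connectivity values; failed fits are NaN."""

    participants: list[str]
    subsets: list[NodeSubset]
    values: np.ndarray
    network_type: str
    failures: list[tuple[str, tuple[str, ...], str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.participants), len(self.subsets)):
            raise ValueError("values shape does not match participants x subsets")


@dataclass
class SubsetAssociation:
    """Per-subset connectivity-outcome correlations plus cohort summaries."""

    r: np.ndarray
    p: np.ndarray
    n_used: np.ndarray
    n_negative: np.ndarray
    flagged: list[tuple[int, str]] = field(default_factory=list)
    median_r: float = np.nan
    iqr_r: tuple[float, float] = (np.nan, np.nan)
    prop_significant: float = np.nan
    alpha: float = 0.05


def enumerate_subsets(
    item_pool, valence: dict[str, str], k: int = 5
) -> list[NodeSubset]:
    """All C(n, k) item combinations in lexicographic (pool) order.

    Each subset carries its count of negative-valence items for the
    valence analysis downstream.
    """
    pool = list(item_pool)
    if k > len(pool):
        raise ValueError(f"k={k} exceeds pool size {len(pool)}")
    return [
        NodeSubset.from_items(combo, valence)
        for combo in itertools.combinations(pool, k)
    ]


class _CompleteCaseEngine:
    """Closed-form per-subset OLS for panels without missing values.

    When every cell is observed, all subsets share the same T-1 lagged
    rows, so the full-pool cross-moment matrices can be computed once per
    participant and each subset's coefficients and residual covariance
    read off from small submatrices.  Algebraically identical to
    :func:`fit_var` + :func:`contemporaneous_from_residuals`.
    """

    def __init__(self, values: np.ndarray):
        V = values
        self.n_rows = V.shape[0] - 1
        Z = np.column_stack([np.ones(self.n_rows), V[:-1]])
        Y = V[1:]
        self.M = Z.T @ Z
        self.C = Z.T @ Y
        self.YtY = Y.T @ Y

    def fit(self, idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return (k x k edges, k x k residual cross-products) for items ``idx``."""
        cols = np.concatenate([[0], idx + 1])
        Ms = self.M[np.ix_(cols, cols)]
        Cs = self.C[np.ix_(cols, idx)]
        B = np.linalg.solve(Ms, Cs)  # (k+1) x k, row 0 = intercepts
        edges = B[1:].T
        rtr = (
            self.YtY[np.ix_(idx, idx)]
            - Cs.T @ B
            - B.T @ Cs
            + B.T @ Ms @ B
        )
        return edges, rtr

    def fit_batch(self, idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Vectorized :meth:`fit` over a (n_subsets, k) index array."""
        n_s, k = idx.shape
        cols = np.concatenate([np.zeros((n_s, 1), dtype=int), idx + 1], axis=1)
        Ms = self.M[cols[:, :, None], cols[:, None, :]]  # (n_s, k+1, k+1)
        Cs = self.C[cols[:, :, None], idx[:, None, :]]  # (n_s, k+1, k)
        B = np.linalg.solve(Ms, Cs)
        edges = np.swapaxes(B[:, 1:, :], 1, 2)
        CtB = np.swapaxes(Cs, 1, 2) @ B
        rtr = (
            self.YtY[idx[:, :, None], idx[:, None, :]]
            - CtB
            - np.swapaxes(CtB, 1, 2)
            + np.swapaxes(B, 1, 2) @ Ms @ B
        )
        return edges, rtr


def _partial_from_crossprod(rtr: np.ndarray) -> np.ndarray:
    P = np.linalg.inv(rtr)
    d = np.sqrt(np.diag(P))
    pc = -P / np.outer(d, d)
    pc = (pc + pc.T) / 2
    np.fill_diagonal(pc, 0.0)
    return pc


def _zero_order_from_crossprod(rtr: np.ndarray) -> np.ndarray:
    sd = np.sqrt(np.diag(rtr))
    cc = rtr / np.outer(sd, sd)
    cc = (cc + cc.T) / 2
    np.fill_diagonal(cc, 0.0)
    return cc


def connectivity_matrix(
    cohort: Cohort,
    subsets: list[NodeSubset],
    network_type: str = "contemporaneous",
    mode: str = "partial",
) -> ConnectivityMatrixResult:
    """Connectivity of every participant in every subset.

    Failed fits (insufficient data, collinearity, singular residual
    covariance) are recorded and leave a NaN cell; they never abort the
    run.  Complete-data panels take a fast closed-form path that is
    algebraically identical to the generic estimator.
    """
    if network_type not in ("directed", "contemporaneous"):
        raise ValueError(f"unknown network_type {network_type!r}")
    n_p, n_s = len(cohort.panels), len(subsets)
    values = np.full((n_p, n_s), np.nan)
    failures: list[tuple[str, tuple[str, ...], str]] = []
    k = subsets[0].k if subsets else 0
    iu = np.triu_indices(k, 1)

    idx_cache: dict[tuple[str, ...], np.ndarray] = {}

    for pi, (pid, panel) in enumerate(cohort.panels.items()):
        complete = bool(panel.observed_mask.all())
        if complete and panel.n_assessments - 1 >= k + 2:
            engine = _CompleteCaseEngine(panel.values)
            key = tuple(panel.item_names)
            if key not in idx_cache:
                col_of = {name: j for j, name in enumerate(panel.item_names)}
                idx_cache[key] = np.array(
                    [[col_of[it] for it in sub.items] for sub in subsets]
                )
            idx = idx_cache[key]
            try:
                edges, rtr = engine.fit_batch(idx)
                if network_type == "directed":
                    values[pi] = edges.sum(axis=(1, 2))
                else:
                    if mode == "partial":
                        P = np.linalg.inv(rtr)
                        d = np.sqrt(
                            np.einsum("sii->si", P)
                        )  # (n_s, k) precision diagonals
                        pc = -P / (d[:, :, None] * d[:, None, :])
                    else:
                        d = np.sqrt(np.einsum("sii->si", rtr))
                        pc = rtr / (d[:, :, None] * d[:, None, :])
                    values[pi] = pc[:, iu[0], iu[1]].sum(axis=1)
                bad = ~np.isfinite(values[pi])
                for si in np.flatnonzero(bad):
                    failures.append(
                        (pid, subsets[si].items, "non-finite connectivity")
                    )
            except np.linalg.LinAlgError:
                # batched solve failed wholesale; fall back subset by subset
                for si, sub in enumerate(subsets):
                    try:
                        e, rt = engine.fit(idx[si])
                        if network_type == "directed":
                            values[pi, si] = e.sum()
                        else:
                            pcm = (
                                _partial_from_crossprod(rt)
                                if mode == "partial"
                                else _zero_order_from_crossprod(rt)
                            )
                            values[pi, si] = pcm[iu].sum()
                        if not np.isfinite(values[pi, si]):
                            raise FitError("non-finite connectivity")
                    except (np.linalg.LinAlgError, FitError) as exc:
                        values[pi, si] = np.nan
                        failures.append((pid, sub.items, str(exc)))
        else:
            for si, sub in enumerate(subsets):
                try:
                    directed, record = fit_var(panel, sub)
                    if network_type == "directed":
                        values[pi, si] = connectivity(directed)
                    else:
                        values[pi, si] = connectivity(
                            contemporaneous_from_residuals(record, mode=mode)
                        )
                except FitError as exc:
                    failures.append((pid, sub.items, str(exc)))
    return ConnectivityMatrixResult(
        participants=list(cohort.panels),
        subsets=list(subsets),
        values=values,
        network_type=network_type,
        failures=failures,
    )


def per_participant_mean(result: ConnectivityMatrixResult) -> dict[str, float]:
    """Mean connectivity over non-missing subsets — the per-person average
    connectivity score."""
    out: dict[str, float] = {}
    for pi, pid in enumerate(result.participants):
        row = result.values[pi]
        ok = np.isfinite(row)
        if not ok.any():
            raise ValueError(f"participant {pid!r} has no successful fits")
        out[pid] = float(row[ok].mean())
    return out


def subset_outcome_associations(
    result: ConnectivityMatrixResult,
    outcome: dict[str, float] | np.ndarray,
    outlier_sd: float = 3.0,
    alpha: float = 0.05,
) -> SubsetAssociation:
    """Correlate each subset's connectivity with an outcome across people.

    Outliers >= ``outlier_sd`` SDs from the mean on either variable are
    removed per analysis (so n varies across subsets).  Two-sided p-values,
    no multiple-testing correction.  Subsets with degenerate data after
    removal are flagged and excluded from the summary statistics.
    """
    if isinstance(outcome, dict):
        y = np.array(
            [outcome.get(p, np.nan) for p in result.participants], dtype=float
        )
    else:
        y = np.asarray(outcome, dtype=float)
        if y.size != len(result.participants):
            raise ValueError("outcome not aligned to participants")
    n_valid = np.isfinite(y).sum()
    if n_valid < 4:
        raise ValueError(f"need >= 4 participants with outcome, got {n_valid}")

    n_s = len(result.subsets)
    r = np.full(n_s, np.nan)
    p = np.full(n_s, np.nan)
    n_used = np.zeros(n_s, dtype=int)
    flagged: list[tuple[int, str]] = []
    for si in range(n_s):
        try:
            r[si], p[si], n_used[si] = outlier_pearson(
                result.values[:, si], y, outlier_sd
            )
        except DegenerateDataError as exc:
            flagged.append((si, str(exc)))
    ok = np.isfinite(r)
    if ok.any():
        q25, q75 = np.percentile(r[ok], [25, 75])
        summary = dict(
            median_r=float(np.median(r[ok])),
            iqr_r=(float(q25), float(q75)),
            prop_significant=float((p[ok] < alpha).mean()),
        )
    else:
        summary = dict(median_r=np.nan, iqr_r=(np.nan, np.nan), prop_significant=np.nan)
    return SubsetAssociation(
        r=r,
        p=p,
        n_used=n_used,
        n_negative=np.array([s.n_negative for s in result.subsets]),
        flagged=flagged,
        alpha=alpha,
        **summary,
    )
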