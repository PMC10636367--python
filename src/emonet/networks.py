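"""Per-participant VAR(1) network estimation.

For a chosen k-node subset, each item at slot t is regressed (OLS, with
intercept, no penalization) on all k items at slot t-1.  The k x k matrix
of lag coefficients is the directed network; the residual correlation
structure gives the contemporaneous network.  Lag pairs must be
consecutive grid slots — a missing slot contributes no row, it is never
bridged by a longer lag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import EmaPanel

__all__ = [
    "NodeSubset",
    "DirectedNetwork",
    "ContemporaneousNetwork",
    "ResidualRecord",
    "fit_var",
    "contemporaneous_from_residuals",
    "connectivity",
    "InsufficientDataError",
    "CollinearityError",
    "FitError",
]

DEFAULT_K = 5
MIN_EXTRA_ROWS = 2  # at least k + 2 usable rows per equation


class FitError(ValueError):
    pass


class InsufficientDataError(FitError):
    pass


class CollinearityError(FitError):
    pass


@dataclass(frozen=True)
class NodeSubset:
    """An ordered selection of items forming one candidate network."""

    items: tuple[str, ...]
    n_negative: int

    def __post_init__(self) -> None:
        if len(set(self.items)) != len(self.items):
            raise FitError("subset items must be unique")
        if len(self.items) < 2:
            raise FitError("subset needs at least 2 items")

    @property
    def k(self) -> int:
        return len(self.items)

    @classmethod
    def from_items(cls, items, valence: dict[str, str]) -> "NodeSubset":
        items = tuple(items)
        return cls(
            items=items,
            n_negative=sum(1 for i in items if valence[i] == "negative"),
        )


@dataclass
class DirectedNetwork:
    """Lag-1 coefficient matrix; entry (i, j) = effect of item j at t-1 on
    item i at t.  The diagonal holds the autoregressive coefficients and
    counts toward connectivity."""

    items: tuple[str, ...]
    edges: np.ndarray
    n_lag_pairs_used: int
    intercepts: np.ndarray | None = None

    @property
    def connectivity(self) -> float:
        """Signed sum of all k^2 edges (diagonal included)."""
        return float(self.edges.sum())


@dataclass
class ContemporaneousNetwork:
    """Symmetric same-moment association of VAR residuals.

    ``mode='partial'`` gives precision-derived partial correlations;
    ``mode='zero_order'`` gives plain Pearson correlations of residual
    pairs.  Diagonal is identically zero.
    """

    items: tuple[str, ...]
    edges: np.ndarray
    mode: str = "partial"
    n_rows_used: int = 0

    @property
    def connectivity(self) -> float:
        """Signed sum of the k(k-1)/2 unique off-diagonal edges."""
        k = self.edges.shape[0]
        iu = np.triu_indices(k, 1)
        return float(self.edges[iu].sum())


@dataclass
class ResidualRecord:
    """Per-equation residuals with the grid slots (t) they belong to."""

    items: tuple[str, ...]
    rows: list[np.ndarray] = field(default_factory=list)
    residuals: list[np.ndarray] = field(default_factory=list)


def _check_collinear(X: np.ndarray, items) -> None:
    """Raise on perfectly collinear lagged predictors, naming the pair."""
    k = len(items)
    if np.linalg.matrix_rank(X) >= X.shape[1]:
        return
    preds = X[:, 1:]  # drop intercept column
    sd = preds.std(axis=0)
    for a in range(k):
        for b in range(a + 1, k):
            if sd[a] == 0 or sd[b] == 0:
                continue
            r = np.corrcoef(preds[:, a], preds[:, b])[0, 1]
            if abs(r) > 1 - 1e-12:
                raise CollinearityError(
                    f"perfectly collinear predictors: {items[a]!r} and {items[b]!r}"
                )
    raise CollinearityError("design matrix is rank deficient")


def fit_var(
    panel: EmaPanel, subset: NodeSubset
) -> tuple[DirectedNetwork, ResidualRecord]:
    """Fit the k-equation lag-1 VAR for ``subset`` on one panel.

    Each equation uses only rows where the outcome at t and *all* k
    predictors at t-1 are observed at consecutive grid slots (listwise per
    equation).  Returns the directed network and the residual record
    needed for the contemporaneous network.

    Raises
    ------
    InsufficientDataError
        If any equation has fewer than k + 2 usable lagged pairs.
    CollinearityError
        If the lagged predictors are perfectly collinear.
    """
    idx = [panel.item_index(it) for it in subset.items]
    V = panel.values[:, idx]
    obs = np.isfinite(V)
    T = V.shape[0]
    k = subset.k
    if T < 2:
        raise InsufficientDataError("insufficient data: panel has < 2 slots")

    lagged_ok = obs[:-1].all(axis=1)  # predictors complete at slot t-1
    edges = np.empty((k, k))
    intercepts = np.empty(k)
    record = ResidualRecord(items=subset.items)
    n_rows_min = T

    for i in range(k):
        rows = np.flatnonzero(lagged_ok & obs[1:, i])  # slot t = rows + 1
        n = rows.size
        if n < k + MIN_EXTRA_ROWS:
            raise InsufficientDataError(
                f"insufficient data: equation for {subset.items[i]!r} has "
                f"{n} lagged pairs, needs >= {k + MIN_EXTRA_ROWS}"
            )
        X = np.column_stack([np.ones(n), V[rows]])
        y = V[rows + 1, i]
        _check_collinear(X, subset.items)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        intercepts[i] = beta[0]
        edges[i] = beta[1:]
        record.rows.append(rows + 1)
        record.residuals.append(y - X @ beta)
        n_rows_min = min(n_rows_min, n)

    if not np.all(np.isfinite(edges)):
        raise FitError("non-finite coefficients in VAR fit")
    net = DirectedNetwork(
        items=subset.items,
        edges=edges,
        n_lag_pairs_used=int(n_rows_min),
        intercepts=intercepts,
    )
    return net, record


def contemporaneous_from_residuals(
    record: ResidualRecord, mode: str = "partial"
) -> ContemporaneousNetwork:
    """Build the contemporaneous network from aligned VAR residuals.

    Residual vectors are aligned on the slots common to all k equations.
    In ``partial`` mode edges are -P_ij / sqrt(P_ii P_jj) with P the
    inverse residual covariance; in ``zero_order`` mode they are plain
    Pearson correlations.
    """
    if mode not in ("partial", "zero_order"):
        raise FitError(f"unknown mode {mode!r}")
    k = len(record.items)
    common = record.rows[0]
    for r in record.rows[1:]:
        common = np.intersect1d(common, r, assume_unique=True)
    if common.size < k + MIN_EXTRA_ROWS:
        raise InsufficientDataError(
            f"insufficient data: only {common.size} common residual rows"
        )
    R = np.empty((common.size, k))
    for j in range(k):
        pos = np.searchsorted(record.rows[j], common)
        R[:, j] = record.residuals[j][pos]

    cov = np.cov(R, rowvar=False)
    if mode == "partial":
        try:
            P = np.linalg.inv(cov)
        except np.linalg.LinAlgError as exc:
            raise FitError("singular residual covariance") from exc
        if not np.all(np.isfinite(P)) or np.linalg.cond(cov) > 1e12:
            raise FitError("singular residual covariance")
        d = np.sqrt(np.diag(P))
        edges = -P / np.outer(d, d)
    else:
        sd = np.sqrt(np.diag(cov))
        if np.any(sd == 0):
            raise FitError("zero-variance residuals")
        edges = cov / np.outer(sd, sd)
    edges = (edges + edges.T) / 2
    np.fill_diagonal(edges, 0.0)
    return ContemporaneousNetwork(
        items=record.items, edges=edges, mode=mode, n_rows_used=int(common.size)
    )


def connectivity(network: DirectedNetwork | ContemporaneousNetwork) -> float:
    """Signed-sum connectivity of either network type."""
    if not np.all(np.isfinite(network.edges)):
        raise FitError("non-finite edge in network")
    return network.connectivity
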