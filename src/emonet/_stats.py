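"""Small shared statistical primitives.

Kept in one place so that the per-subset association machinery and the
subject-level ``correlate`` operation are guaranteed to agree exactly.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = ["outlier_pearson", "zscore", "DegenerateDataError"]


class DegenerateDataError(ValueError):
    """Zero variance (or otherwise unusable) data for a statistic."""


def zscore(x: np.ndarray, ddof: int = 1) -> np.ndarray:
    """Standardize to mean 0, SD 1 (sample SD by default)."""
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=ddof)
    if not np.isfinite(sd) or sd == 0:
        raise DegenerateDataError("zero variance, cannot standardize")
    return (x - x.mean()) / sd


def outlier_pearson(
    x: np.ndarray, y: np.ndarray, outlier_sd: float = 3.0
) -> tuple[float, float, int]:
    """Pearson r and two-sided p after joint outlier removal.

    Pairs with a missing entry are dropped first.  Then any pair whose x- or
    y-value lies >= ``outlier_sd`` sample SDs from that analysis's own mean
    is removed, in a single pass.  The p-value comes from the t reference
    distribution with ``n_used - 2`` degrees of freedom.

    Returns ``(r, p, n_used)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must be aligned")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 4:
        raise DegenerateDataError(f"need >= 4 complete pairs, got {x.size}")
    if outlier_sd is not None and np.isfinite(outlier_sd):
        zx = _safe_z(x)
        zy = _safe_z(y)
        inliers = (np.abs(zx) < outlier_sd) & (np.abs(zy) < outlier_sd)
        x, y = x[inliers], y[inliers]
    n = x.size
    if n < 3 or x.std() == 0 or y.std() == 0:
        raise DegenerateDataError("zero variance after outlier removal")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), int(n)


def _safe_z(v: np.ndarray) -> np.ndarray:
    sd = v.std(ddof=1)
    if sd == 0:
        return np.zeros_like(v)
    return (v - v.mean()) / sd
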