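"""Shared rank/correlation primitives."""

from __future__ import annotations

import numpy as np
from scipy import stats


def rank_columns(a: np.ndarray) -> np.ndarray:
    """Average-tie ranks of each column of a 2-D array."""
    return stats.rankdata(a, axis=0, method="average")


def pairwise_spearman(a: np.ndarray) -> np.ndarray:
    """k x k Spearman correlation matrix of the columns of ``a`` (n x k).

    Uses a fast rank-then-Pearson path when ``a`` is complete and falls back
    to pairwise-complete computation when missing values are present.
    """
    a = np.asarray(a, dtype=float)
    k = a.shape[1]
    if not np.isnan(a).any():
        r = rank_columns(a)
        with np.errstate(invalid="ignore"):
            c = np.corrcoef(r, rowvar=False)
        return np.atleast_2d(c)
    out = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            mask = np.isfinite(a[:, i]) & np.isfinite(a[:, j])
            if mask.sum() < 3:
                rho = np.nan
            else:
                rho = stats.spearmanr(a[mask, i], a[mask, j]).statistic
            out[i, j] = out[j, i] = rho
    return out


def spearman_cross(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """p x q Spearman correlations between columns of ``a`` (n x p) and
    ``b`` (n x q); inputs must be complete (no NaN)."""
    ra = rank_columns(np.asarray(a, dtype=float))
    rb = rank_columns(np.asarray(b, dtype=float))
    ra = ra - ra.mean(axis=0)
    rb = rb - rb.mean(axis=0)
    denom = np.outer(
        np.sqrt((ra**2).sum(axis=0)), np.sqrt((rb**2).sum(axis=0))
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        return (ra.T @ rb) / denom
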