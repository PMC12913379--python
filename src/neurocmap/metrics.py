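"""Per-signature QC and activity metrics.

For every replicate set the pipeline reports:

* **CC** (replicate correlation): the 75th percentile of all pairwise
  Spearman correlations among the replicate level-4 profiles.
* **SS** (signature strength): the number of panel genes whose
  replicate-moderated z-score ``Za = mean(z) * sqrt(n)`` exceeds 2 in
  absolute value (strict inequality).
* **TAS** (transcriptional activity score):
  ``sqrt(SS * max(CC, 0) / G)`` with G the panel size, combining response
  magnitude (SS) with replicate consistency (CC) on [0, 1].

An upper-tail F-distribution helper is included for one-way group
comparisons in reports.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special

from ._stats import pairwise_spearman
from .core import PANEL_SIZE, ExpressionMatrix

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SignatureMetrics:
    """QC metrics for one replicate set."""

    cc: float
    ss: int
    tas: float
    n_replicates: int
    G: int = PANEL_SIZE


def replicate_correlation(reps: pd.DataFrame | np.ndarray) -> float:
    """75th quantile of pairwise Spearman correlations among replicates.

    Uses the linear-interpolation quantile between order statistics. A
    single replicate has no pairs; its CC is defined as 0 with a warning.
    """
    arr = np.asarray(reps, dtype=float)
    n = arr.shape[1]
    if n < 2:
        log.warning("replicate_correlation: single replicate, CC defined as 0")
        return 0.0
    corr = pairwise_spearman(arr)
    iu = np.triu_indices(n, k=1)
    pairs = corr[iu]
    pairs = pairs[np.isfinite(pairs)]
    if len(pairs) == 0:
        return 0.0
    return float(np.percentile(pairs, 75, method="linear"))


def moderated_z(reps: pd.DataFrame | np.ndarray, za_mode: str = "sqrt_n_mean") -> np.ndarray:
    """Replicate-moderated z-scores.

    ``sqrt_n_mean`` (default): ``Za = mean(z) * sqrt(n)``, the standard
    error-scaled replicate mean. ``n_mean`` is the literal alternative
    ``Za = mean(z) * n``, kept as a configurable interpretation flag.
    """
    arr = np.asarray(reps, dtype=float)
    n = arr.shape[1]
    mean_z = np.nanmean(arr, axis=1)
    if za_mode == "sqrt_n_mean":
        return mean_z * math.sqrt(n)
    if za_mode == "n_mean":
        return mean_z * n
    raise ValueError(f"unknown za_mode {za_mode!r}")


def signature_strength(
    reps: pd.DataFrame | np.ndarray,
    threshold: float = 2.0,
    za_mode: str = "sqrt_n_mean",
) -> int:
    """Count of genes whose moderated z exceeds the threshold, strictly."""
    za = moderated_z(reps, za_mode=za_mode)
    return int(np.sum(np.abs(za[np.isfinite(za)]) > threshold))


def tas(ss: float, cc: float, G: int = PANEL_SIZE, mode: str = "sqrt") -> float:
    """Transcriptional activity score on [0, 1].

    ``sqrt`` (default): ``sqrt(ss * max(cc, 0) / G)``. ``linear`` is the
    unscaled product ``ss * max(cc, 0) / G``, kept as an interpretation
    flag. Negative CC is clamped to zero: anti-correlated replicates carry
    no evidence of activity.
    """
    if not 0 <= ss <= G:
        raise ValueError(f"ss must be in [0, {G}], got {ss}")
    if not -1.0000001 <= cc <= 1.0000001:
        raise ValueError(f"cc must be in [-1, 1], got {cc}")
    frac = ss * max(cc, 0.0) / G
    if mode == "sqrt":
        return float(np.sqrt(frac))
    if mode == "linear":
        return float(frac)
    raise ValueError(f"unknown tas mode {mode!r}")


def compute_signature_metrics(
    z: ExpressionMatrix,
    groups: pd.Series,
    G: int | None = None,
    za_mode: str = "sqrt_n_mean",
    tas_mode: str = "sqrt",
) -> pd.DataFrame:
    """CC, SS, TAS and replicate count for every replicate group.

    ``groups`` maps sample id -> replicate-group key; metrics are computed
    on the level-4 columns of each group over all rows of ``z`` (pass a
    matrix restricted to the non-invariant panel genes for panel-scaled
    scores). Returns one row per group, indexed by group key.
    """
    if G is None:
        G = z.n_genes
    rows = {}
    order: list[str] = []
    for s in z.values.columns:
        g = groups.get(s)
        if g is not None and g not in rows:
            rows[g] = []
            order.append(g)
        if g is not None:
            rows[g].append(s)
    records = []
    for g in order:
        cols = z.values[rows[g]]
        n = cols.shape[1]
        cc = replicate_correlation(cols) if n >= 2 else 0.0
        ss = signature_strength(cols, za_mode=za_mode)
        records.append(
            {
                "replicate_group": g,
                "cc": cc,
                "ss": ss,
                "tas": tas(ss, cc, G=G, mode=tas_mode),
                "n_replicates": n,
            }
        )
    return pd.DataFrame(records).set_index("replicate_group")


def f_test_pvalue(f_statistic: float, df1: int, df2: int) -> float:
    """Upper-tail probability ``P(F_{df1, df2} > f)``.

    Evaluated through the regularized incomplete beta function
    ``I_{df2/(df2 + df1 f)}(df2/2, df1/2)``.
    """
    if df1 < 1 or df2 < 1:
        raise ValueError(f"degrees of freedom must be >= 1, got ({df1}, {df2})")
    if f_statistic < 0:
        raise ValueError(f"F statistic must be nonnegative, got {f_statistic}")
    x = df2 / (df2 + df1 * f_statistic)
    return float(special.betainc(df2 / 2.0, df1 / 2.0, x))
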