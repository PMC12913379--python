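"""Five-level plate processing for bead-based expression screens.

Level 1 is the raw bead-level fluorescence table. Level 2 collapses beads to
per-(gene, well) median fluorescence (MFI). Level 3 calibrates each well
against the 10-level invariant-probe ladder and quantile-normalizes wells
within each detection plate. Level 4 converts to gene-wise robust z-scores
against all samples on the plate. Level 5 collapses biological replicates
into one signature per replicate group with correlation-derived weights.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.isotonic import IsotonicRegression
from statsmodels.nonparametric.smoothers_lowess import lowess

from ._stats import pairwise_spearman
from .core import ExpressionMatrix, N_INVARIANT_LEVELS, _require_columns

log = logging.getLogger(__name__)

BEAD_COLUMNS = ("plate_id", "well", "bead_barcode", "fluorescence_intensity")

#: Normal-consistency scale factor for the median absolute deviation.
MAD_SCALE = 1.4826
#: Floor applied to nonzero MADs to avoid numerical blow-up.
MAD_FLOOR = 1e-6
#: Floor for replicate-collapse weights before normalization.
WEIGHT_FLOOR = 0.01


def default_invariant_reference(
    n_levels: int = N_INVARIANT_LEVELS, base_exponent: int = 6
) -> pd.Series:
    """Canonical expected fluorescence of each invariant ladder level.

    A geometric ladder ``2**(base_exponent + level - 1)`` for levels
    1..n_levels; only its strictly monotone shape matters for calibration.
    """
    levels = np.arange(1, n_levels + 1)
    return pd.Series(
        2.0 ** (base_exponent + levels - 1), index=pd.Index(levels, name="level"),
        name="canonical_value",
    )


def level1_to_level2(beads: pd.DataFrame, panel: pd.DataFrame) -> ExpressionMatrix:
    """Collapse bead-level fluorescence to median fluorescence intensity.

    Cell ``(gene, well)`` is the median FI across all beads carrying that
    gene's barcode in that well; gene/well combinations with zero beads are
    missing. Wells are identified by ``plate_id:well`` so that well labels
    may repeat across plates.
    """
    _require_columns(beads, BEAD_COLUMNS, "bead table")
    barcode_to_gene = dict(
        zip(panel["bead_barcode"].astype(str), panel["gene_id"].astype(str))
    )
    codes = beads["bead_barcode"].astype(str)
    unknown = set(codes.unique()) - set(barcode_to_gene)
    if unknown:
        raise ValueError(f"unknown bead barcodes: {sorted(unknown)[:5]}")
    sample = (
        beads["plate_id"].astype(str) + ":" + beads["well"].astype(str)
    ).rename("sample_id")
    gene = codes.map(barcode_to_gene).rename("gene_id")
    fi = pd.to_numeric(beads["fluorescence_intensity"])
    if (fi < 0).any():
        raise ValueError("negative fluorescence intensities")
    mfi = fi.groupby([gene.to_numpy(), sample.to_numpy()]).median()
    values = mfi.unstack(level=1)
    # keep full panel gene order; genes never measured become all-missing rows
    values = values.reindex(panel["gene_id"].astype(str).to_numpy())
    values.index.name = "id"
    row_meta = panel.set_index(panel["gene_id"].astype(str)).drop(columns="gene_id")
    row_meta = row_meta.loc[values.index]
    col_meta = pd.DataFrame(
        {
            "plate_id": [s.rsplit(":", 1)[0] for s in values.columns],
            "well": [s.rsplit(":", 1)[1] for s in values.columns],
        },
        index=values.columns,
    )
    return ExpressionMatrix(values=values, row_meta=row_meta, col_meta=col_meta, level=2)


@dataclass
class CalibrationResult:
    """Invariant-ladder calibration output: the calibrated matrix plus a
    per-well QC table (levels used, max |residual| in log2 units, pass flag)."""

    matrix: ExpressionMatrix
    well_qc: pd.DataFrame


def _calibration_points(
    obs: np.ndarray, canon: np.ndarray, lowess_min_points: int = 7,
    lowess_frac: float = 0.9,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Monotone (observed -> canonical) calibration nodes on the log2 scale.

    Non-monotone observed medians are isotonic-adjusted; with at least
    ``lowess_min_points`` nodes a loess-style smooth (span ``lowess_frac``)
    replaces the raw canonical targets.
    """
    adjusted = False
    if np.any(np.diff(obs) <= 0):
        adjusted = True
        obs = IsotonicRegression(increasing=True).fit_transform(
            np.arange(len(obs)), obs
        )
        # break exact ties so interpolation nodes stay strictly increasing
        for i in range(1, len(obs)):
            if obs[i] <= obs[i - 1]:
                obs[i] = obs[i - 1] + 1e-9
    y = canon.astype(float)
    if len(obs) >= lowess_min_points:
        y = lowess(canon, obs, frac=lowess_frac, return_sorted=False)
        y = np.maximum.accumulate(y)  # guard monotonicity of the smooth
    return obs, y, adjusted


def _apply_piecewise(x: np.ndarray, nodes_x: np.ndarray, nodes_y: np.ndarray) -> np.ndarray:
    """Piecewise-linear map through the nodes with linear end extrapolation."""
    out = np.interp(x, nodes_x, nodes_y)
    lo_slope = (nodes_y[1] - nodes_y[0]) / (nodes_x[1] - nodes_x[0])
    hi_slope = (nodes_y[-1] - nodes_y[-2]) / (nodes_x[-1] - nodes_x[-2])
    below = x < nodes_x[0]
    above = x > nodes_x[-1]
    out[below] = nodes_y[0] + (x[below] - nodes_x[0]) * lo_slope
    out[above] = nodes_y[-1] + (x[above] - nodes_x[-1]) * hi_slope
    return out


def invariant_normalize(
    mfi: ExpressionMatrix,
    reference: pd.Series | None = None,
    min_levels: int = 2,
) -> CalibrationResult:
    """Calibrate every well against the invariant-probe ladder.

    For each well the median MFI of each invariant level set defines a
    monotone calibration curve to the canonical ladder values; the curve is
    fit and applied on the log2(FI + 1) scale and mapped back to
    fluorescence scale. Wells with fewer than ``min_levels`` usable ladder
    levels are flagged ``passed = False`` and left unchanged.
    """
    if reference is None:
        reference = default_invariant_reference()
    if not np.all(np.diff(reference.to_numpy()) > 0):
        raise ValueError("canonical invariant values must be strictly increasing")
    inv_levels = mfi.row_meta["invariant_level"].astype(int)
    if (inv_levels > 0).sum() == 0:
        raise ValueError("matrix has no invariant probes to calibrate against")

    logv = np.log2(mfi.values.to_numpy() + 1.0)
    out = logv.copy()
    canon_log = np.log2(reference.to_numpy() + 1.0)
    level_masks = [
        (inv_levels == lv).to_numpy() for lv in reference.index.astype(int)
    ]
    qc_rows = []
    for j, sample in enumerate(mfi.values.columns):
        med = np.array(
            [np.nanmedian(logv[m, j]) if m.any() else np.nan for m in level_masks]
        )
        usable = np.isfinite(med)
        n_usable = int(usable.sum())
        if n_usable < min_levels:
            qc_rows.append((sample, n_usable, np.nan, False, False))
            continue
        obs, canon = med[usable], canon_log[usable]
        nodes_x, nodes_y, adjusted = _calibration_points(obs, canon)
        if adjusted:
            log.warning(
                "invariant_normalize: non-monotone invariant medians in %s; "
                "isotonic pre-adjustment applied", sample,
            )
        out[:, j] = _apply_piecewise(out[:, j], nodes_x, nodes_y)
        post_med = np.array(
            [np.nanmedian(out[m, j]) if m.any() else np.nan for m in level_masks]
        )
        resid = np.nanmax(np.abs(post_med[usable] - canon_log[usable]))
        qc_rows.append((sample, n_usable, float(resid), adjusted, True))

    values = pd.DataFrame(
        np.maximum(2.0**out - 1.0, 0.0),
        index=mfi.values.index,
        columns=mfi.values.columns,
    )
    failed_wells = [r[0] for r in qc_rows if not r[4]]
    if failed_wells:  # failed wells pass through bit-identical
        values[failed_wells] = mfi.values[failed_wells]
    qc = pd.DataFrame(
        qc_rows,
        columns=["sample_id", "n_invariant_levels", "max_abs_residual_log2",
                 "isotonic_adjusted", "passed"],
    ).set_index("sample_id")
    n_failed = int((~qc["passed"]).sum())
    if n_failed:
        log.warning("invariant_normalize: %d wells failed ladder QC", n_failed)
    matrix = ExpressionMatrix(
        values=values, row_meta=mfi.row_meta, col_meta=mfi.col_meta, level=mfi.level
    )
    return CalibrationResult(matrix=matrix, well_qc=qc)


def _qn_complete(block: np.ndarray) -> np.ndarray:
    """Exact quantile normalization of a complete genes x wells block:
    sorted values of every column become the across-column mean of sorted
    values; tied input values receive the mean of their target quantiles."""
    n, m = block.shape
    ref = np.sort(block, axis=0).mean(axis=1)
    out = np.empty_like(block)
    for j in range(m):
        col = block[:, j]
        order = np.argsort(col, kind="mergesort")
        sorted_vals = col[order]
        # tie runs share the mean of the reference values they span
        boundaries = np.flatnonzero(np.r_[True, sorted_vals[1:] != sorted_vals[:-1]])
        sums = np.add.reduceat(ref, boundaries)
        counts = np.diff(np.r_[boundaries, n])
        tie_means = np.repeat(sums / counts, counts)
        out[order, j] = tie_means
    return out


def _qn_with_missing(block: np.ndarray) -> np.ndarray:
    """Quantile normalization tolerating missing cells: each column's
    non-missing values are mapped through the mean quantile function
    evaluated on a common probability grid; missing cells stay missing."""
    n, m = block.shape
    probs = np.linspace(0.0, 1.0, n)
    qfuns = []
    for j in range(m):
        v = np.sort(block[np.isfinite(block[:, j]), j])
        if len(v) == 0:
            qfuns.append(np.full(n, np.nan))
        elif len(v) == 1:
            qfuns.append(np.full(n, v[0]))
        else:
            qfuns.append(np.interp(probs, np.linspace(0, 1, len(v)), v))
    ref = np.nanmean(np.column_stack(qfuns), axis=1)
    out = np.full_like(block, np.nan)
    for j in range(m):
        mask = np.isfinite(block[:, j])
        k = mask.sum()
        if k == 0:
            continue
        ranks = stats.rankdata(block[mask, j], method="average")
        p = (ranks - 1.0) / max(k - 1.0, 1.0)
        out[mask, j] = np.interp(p, probs, ref)
    return out


def quantile_normalize(
    matrix: ExpressionMatrix, plate_groups: pd.Series | None = None
) -> ExpressionMatrix:
    """Quantile-normalize wells within each detection plate.

    After normalization every column of a plate has the same empirical
    distribution (the mean of the plate's sorted columns). Plates with a
    single well are returned unchanged with a warning.
    """
    groups = _resolve_groups(matrix, plate_groups)
    values = matrix.values.to_numpy().copy()
    for plate, cols in groups.groupby(groups).groups.items():
        idx = [matrix.values.columns.get_loc(c) for c in cols]
        if len(idx) < 2:
            warnings.warn(f"plate {plate!r} has a single well; left unchanged")
            continue
        block = values[:, idx]
        if np.isnan(block).any():
            values[:, idx] = _qn_with_missing(block)
        else:
            values[:, idx] = _qn_complete(block)
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=matrix.values.index, columns=matrix.values.columns),
        row_meta=matrix.row_meta,
        col_meta=matrix.col_meta,
        level=3,
    )


def robust_zscore(
    matrix: ExpressionMatrix,
    plate_groups: pd.Series | None = None,
    min_samples: int = 3,
) -> ExpressionMatrix:
    """Gene-wise robust z-scores with the plate as reference distribution.

    ``z = (x - median) / (1.4826 * MAD)`` with median and MAD taken across
    all samples on the sample's plate. Constant rows yield z = 0; nonzero
    MADs are floored at 1e-6.
    """
    groups = _resolve_groups(matrix, plate_groups)
    values = matrix.values.to_numpy()
    out = np.full_like(values, np.nan)
    for plate, cols in groups.groupby(groups).groups.items():
        idx = [matrix.values.columns.get_loc(c) for c in cols]
        if len(idx) < min_samples:
            raise ValueError(
                f"plate {plate!r} has {len(idx)} samples; need >= {min_samples} "
                "for a robust reference distribution"
            )
        block = values[:, idx]
        med = np.nanmedian(block, axis=1, keepdims=True)
        mad = np.nanmedian(np.abs(block - med), axis=1, keepdims=True)
        denom = MAD_SCALE * np.maximum(mad, MAD_FLOOR)
        z = (block - med) / denom
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            constant = np.nanmax(block, axis=1) == np.nanmin(block, axis=1)
        z[constant] = np.where(np.isfinite(block[constant]), 0.0, np.nan)
        out[:, idx] = z
    return ExpressionMatrix(
        values=pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns),
        row_meta=matrix.row_meta,
        col_meta=matrix.col_meta,
        level=4,
    )


def collapse_replicates(z: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    """Collapse replicate level-4 columns into one level-5 signature.

    Each replicate is weighted by its mean Spearman correlation to the other
    replicates (floored at 0.01, normalized to sum to one). One replicate
    passes through unchanged; two replicates average with equal weights.

    Returns
    -------
    (signature, weights)
    """
    n = z.shape[1]
    if n < 1:
        raise ValueError("no replicate columns to collapse")
    if n == 1:
        return z.iloc[:, 0].copy(), pd.Series([1.0], index=z.columns)
    if n == 2:
        w = pd.Series([0.5, 0.5], index=z.columns)
    else:
        corr = pairwise_spearman(z.to_numpy())
        np.fill_diagonal(corr, np.nan)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean_corr = np.nanmean(corr, axis=1)
        wv = np.maximum(np.nan_to_num(mean_corr, nan=WEIGHT_FLOOR), WEIGHT_FLOOR)
        w = pd.Series(wv / wv.sum(), index=z.columns)
    arr = z.to_numpy()
    wvec = w.to_numpy()
    finite = np.isfinite(arr)
    wmat = np.where(finite, wvec, 0.0)
    denom = wmat.sum(axis=1)
    num = np.nansum(arr * wmat, axis=1)
    with np.errstate(invalid="ignore"):
        sig = np.where(denom > 0, num / denom, np.nan)
    return pd.Series(sig, index=z.index), w


def collapse_all(
    z: ExpressionMatrix, groups: pd.Series
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Collapse every replicate group of a level-4 matrix.

    ``groups`` maps sample id -> replicate-group key. Returns the level-5
    matrix (one column per group, in first-appearance order) and the
    per-replicate weight table.
    """
    order: list[str] = []
    seen = set()
    for s in z.values.columns:
        g = groups.get(s)
        if g is not None and g not in seen:
            seen.add(g)
            order.append(g)
    cols = {}
    weight_rows = []
    meta_rows = []
    agg_cols = [c for c in ("plate_id", "well") if c in z.col_meta.columns]
    for g in order:
        members = [s for s in z.values.columns if groups.get(s) == g]
        sig, w = collapse_replicates(z.values[members])
        cols[g] = sig
        for s, wi in w.items():
            weight_rows.append({"replicate_group": g, "sample_id": s, "weight": wi})
        meta = z.col_meta.loc[members[0]].drop(labels=agg_cols, errors="ignore")
        meta["n_replicates"] = len(members)
        meta_rows.append(meta.rename(g))
    values = pd.DataFrame(cols)
    col_meta = pd.DataFrame(meta_rows) if meta_rows else pd.DataFrame(index=values.columns)
    matrix = ExpressionMatrix(
        values=values, row_meta=z.row_meta, col_meta=col_meta, level=5
    )
    return matrix, pd.DataFrame(weight_rows)


def _resolve_groups(matrix: ExpressionMatrix, plate_groups: pd.Series | None) -> pd.Series:
    if plate_groups is None:
        if "plate_id" not in matrix.col_meta.columns:
            raise ValueError("no plate grouping given and col_meta lacks 'plate_id'")
        plate_groups = matrix.col_meta["plate_id"]
    return plate_groups.reindex(matrix.values.columns)
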