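"""Probe- and signature-level recall validation.

Probe recall asks whether each panel probe's measurements across a set of
reference cell lines track its own gene in an orthogonal RNA-seq reference
better than they track unrelated genes: the probe's Spearman correlation to
every reference gene is computed, and the recall rank is the percentage of
reference genes correlating *strictly* better than the matched gene. Small
ranks mean a faithful probe; the default pass threshold is a recall rank
below 5%.

Signature recall asks whether a compound's signature, queried against an
external signature collection by Spearman correlation, retrieves that same
compound's signatures near the top. Signatures must first pass a TAS
activity gate (default 0.212) before recall is evaluated against a rank
threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._stats import spearman_cross

log = logging.getLogger(__name__)

PASS_THRESHOLD_PCT = 5.0
TAS_ACTIVITY_THRESHOLD = 0.212
SIGNATURE_RANK_THRESHOLD = 190


@dataclass
class RecallReport:
    """Per-probe recall against an RNA-seq reference."""

    per_probe: pd.DataFrame
    pass_threshold_pct: float
    n_excluded: int = 0
    excluded: list = field(default_factory=list)

    @property
    def n_total(self) -> int:
        return len(self.per_probe)

    @property
    def n_passed(self) -> int:
        return int(self.per_probe["passed"].sum())

    @property
    def fraction_passed(self) -> float:
        return self.n_passed / self.n_total if self.n_total else np.nan

    def summary(self) -> dict:
        out = {
            "n_passed": self.n_passed,
            "n_total": self.n_total,
            "fraction_passed": self.fraction_passed,
            "n_excluded": self.n_excluded,
        }
        if "low_expression" in self.per_probe.columns:
            failed = self.per_probe[~self.per_probe["passed"]]
            out["n_failed"] = len(failed)
            out["n_failed_low_expression"] = int(failed["low_expression"].sum())
        return out


def probe_recall(
    panel_matrix: pd.DataFrame,
    rnaseq: pd.DataFrame,
    pass_threshold_pct: float = PASS_THRESHOLD_PCT,
) -> RecallReport:
    """Recall rank of every panel probe against an RNA-seq reference.

    Both matrices are genes x cell lines; columns are aligned on the shared
    cell-line ids (at least 3 required). Probes whose matched gene is absent
    from the reference or constant across the shared cell lines are excluded
    and listed in the report (they have no defined rank).
    """
    shared = [c for c in panel_matrix.columns if c in rnaseq.columns]
    if len(shared) < 3:
        raise ValueError(
            f"only {len(shared)} shared cell lines between panel and reference; need >= 3"
        )
    pm = panel_matrix[shared]
    rs = rnaseq[shared]

    excluded = []
    keep = []
    for g in pm.index:
        if g not in rs.index:
            excluded.append((g, "absent_from_reference"))
        elif np.nanstd(rs.loc[g].to_numpy()) == 0:
            excluded.append((g, "constant_in_reference"))
        elif np.nanstd(pm.loc[g].to_numpy()) == 0:
            excluded.append((g, "constant_in_panel"))
        else:
            keep.append(g)
    if excluded:
        log.info("probe_recall: %d probes excluded (%s ...)", len(excluded), excluded[:3])
    if not keep:
        raise ValueError("no probes with a usable matched reference gene")

    # probes x reference-genes Spearman correlations across shared cell lines
    corr = spearman_cross(pm.loc[keep].T.to_numpy(), rs.T.to_numpy())
    ref_genes = rs.index.to_numpy()
    n_ref = len(ref_genes)
    rows = []
    for i, g in enumerate(keep):
        r = corr[i]
        matched = r[np.flatnonzero(ref_genes == g)[0]]
        higher = int(np.sum(r[np.isfinite(r)] > matched))
        rank_pct = 100.0 * higher / n_ref
        rows.append(
            {
                "probe": g,
                "spearman_r": float(matched),
                "recall_rank_pct": rank_pct,
                "passed": rank_pct < pass_threshold_pct,
            }
        )
    per_probe = pd.DataFrame(rows).set_index("probe")
    return RecallReport(
        per_probe=per_probe,
        pass_threshold_pct=pass_threshold_pct,
        n_excluded=len(excluded),
        excluded=excluded,
    )


def annotate_failures(
    report: RecallReport, rnaseq: pd.DataFrame, low_expr_threshold: float = 1.0
) -> RecallReport:
    """Annotate failed probes whose reference gene is lowly expressed.

    A failed probe is flagged ``low_expression`` when its matched gene's
    mean reference value (log2 RPKM scale) falls below the threshold — a
    poor recall rank for such genes reflects absent signal rather than a
    faulty probe.
    """
    means = rnaseq.mean(axis=1)
    per = report.per_probe.copy()
    per["low_expression"] = False
    failed = per.index[~per["passed"]]
    for g in failed:
        if g in means.index and means[g] < low_expr_threshold:
            per.loc[g, "low_expression"] = True
    return RecallReport(
        per_probe=per,
        pass_threshold_pct=report.pass_threshold_pct,
        n_excluded=report.n_excluded,
        excluded=report.excluded,
    )


def signature_recall(
    test_signatures: pd.DataFrame,
    test_meta: pd.DataFrame,
    reference_signatures: pd.DataFrame,
    reference_meta: pd.DataFrame,
    tas_threshold: float = TAS_ACTIVITY_THRESHOLD,
    rank_threshold: int = SIGNATURE_RANK_THRESHOLD,
) -> pd.DataFrame:
    """Compound recall of test signatures against a reference collection.

    ``test_signatures`` / ``reference_signatures`` are genes x signatures
    matrices sharing a gene space (intersection used); ``test_meta`` needs
    columns ``pert_id`` and ``tas`` (indexed by signature id),
    ``reference_meta`` needs ``pert_id``. For each test signature that
    passes the TAS activity gate, Spearman correlations to every reference
    signature are ranked descending; the best rank among the matched
    compound's reference signatures is compared to ``rank_threshold``.

    Returns one row per test signature with columns ``pert_id``, ``tas``,
    ``active``, ``best_rank``, ``recalled``, ``n_reference``.
    """
    shared_perts = set(test_meta["pert_id"]) & set(reference_meta["pert_id"])
    if not shared_perts:
        raise ValueError("no compounds shared between test and reference collections")
    genes = test_signatures.index.intersection(reference_signatures.index)
    if len(genes) < 10:
        raise ValueError(f"shared gene space too small ({len(genes)} genes)")
    ts = test_signatures.loc[genes]
    rs = reference_signatures.loc[genes]
    corr = spearman_cross(ts.to_numpy(), rs.to_numpy())
    ref_perts = reference_meta["pert_id"].reindex(rs.columns).to_numpy()

    rows = []
    for i, sid in enumerate(ts.columns):
        pert = test_meta.loc[sid, "pert_id"]
        tas_val = float(test_meta.loc[sid, "tas"])
        active = tas_val >= tas_threshold
        best_rank = np.nan
        recalled = False
        if active and pert in shared_perts:
            # rank 1 = highest correlation; ties share the best (min) rank
            r = corr[i]
            order = np.argsort(-r, kind="mergesort")
            ranks = np.empty(len(r), dtype=int)
            ranks[order] = np.arange(1, len(r) + 1)
            matched = ranks[ref_perts == pert]
            if len(matched):
                best_rank = int(matched.min())
                recalled = best_rank <= rank_threshold
        rows.append(
            {
                "signature_id": sid,
                "pert_id": pert,
                "tas": tas_val,
                "active": active,
                "best_rank": best_rank,
                "recalled": recalled,
                "n_reference": rs.shape[1],
            }
        )
    return pd.DataFrame(rows).set_index("signature_id")
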