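"""Up/down gene-set connectivity scoring against signature collections.

A query is a pair of disjoint gene lists (up- and down-regulated). Against
each reference signature (a level-5 z-score vector) the engine computes:

* **WTCS** — the weighted two-sided enrichment score: weighted
  Kolmogorov-Smirnov enrichment (GSEA-style running sum, hit increments
  weighted by |z|) of the up and the down set against the signature ranked
  by descending z; ``(ES_up - ES_down) / 2`` when the two have opposite
  signs, else 0.
* **NCS** — WTCS normalized by the mean |WTCS| of same-sign scores within a
  (cell line, perturbagen type) group.
* **tau** — the signed percentile of |NCS| against a reference
  ("touchstone") NCS distribution from the same cell line, on [-100, 100];
  positive tau marks mimics of the query, negative tau reversers.

Per-perturbagen median tau across cell lines ranks compounds as mimics
(descending) or reversers (ascending).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._stats import spearman_cross
from .core import ExpressionMatrix

log = logging.getLogger(__name__)

#: Default bounds on each query gene-list size.
MIN_QUERY_GENES = 10
MAX_QUERY_GENES = 150

#: Perturbagen types included in the tau reference distribution by default
#: (vehicle controls are excluded: they carry no biological connectivity).
DEFAULT_TOUCHSTONE_TYPES = ("CP", "KD", "OE")


@dataclass(frozen=True)
class QuerySignature:
    """Disjoint up/down gene lists defining a transcriptional query."""

    up: tuple[str, ...]
    down: tuple[str, ...]

    def __post_init__(self) -> None:
        overlap = set(self.up) & set(self.down)
        if overlap:
            raise ValueError(f"up/down lists overlap: {sorted(overlap)[:5]}")

    def validate_sizes(
        self, min_genes: int = MIN_QUERY_GENES, max_genes: int = MAX_QUERY_GENES
    ) -> "QuerySignature":
        for name, genes in (("up", self.up), ("down", self.down)):
            if genes and not min_genes <= len(genes) <= max_genes:
                raise ValueError(
                    f"{name} list has {len(genes)} genes; allowed "
                    f"[{min_genes}, {max_genes}]"
                )
        return self

    def swapped(self) -> "QuerySignature":
        return QuerySignature(up=self.down, down=self.up)


def prepare_query_from_degs(
    degs: pd.DataFrame,
    n_up: int = 137,
    n_down: int = 150,
    significance_threshold: float | None = None,
    panel_genes=None,
    min_genes: int = MIN_QUERY_GENES,
    max_genes: int = MAX_QUERY_GENES,
) -> QuerySignature:
    """Build a query from a differential-expression table.

    After the optional significance filter, the up list is the top ``n_up``
    genes by descending log2 fold change among positives and the down list
    the top ``n_down`` by ascending log2 fold change among negatives. Genes
    absent from ``panel_genes`` (when given) are dropped first, with the
    count logged.
    """
    df = degs.copy()
    if significance_threshold is not None:
        if "significance" not in df.columns:
            raise ValueError("DEG table has no significance column to filter on")
        df = df[df["significance"] <= significance_threshold]
    if df.empty:
        raise ValueError("DEG table is empty after the significance filter")
    if panel_genes is not None:
        panel_set = {str(g).upper() for g in panel_genes}
        before = len(df)
        df = df[df["gene_id"].isin(panel_set)]
        dropped = before - len(df)
        if dropped:
            log.info(
                "prepare_query_from_degs: %d of %d DEGs absent from the panel, dropped",
                dropped, before,
            )
    pos = df[df["log2_fold_change"] > 0].sort_values(
        ["log2_fold_change", "gene_id"], ascending=[False, True]
    )
    neg = df[df["log2_fold_change"] < 0].sort_values(
        ["log2_fold_change", "gene_id"], ascending=[True, True]
    )
    up = tuple(pos["gene_id"].head(n_up))
    down = tuple(neg["gene_id"].head(n_down))
    if len(up) < min_genes or len(down) < min_genes:
        raise ValueError(
            f"query too small after filtering: {len(up)} up / {len(down)} down "
            f"genes surviving (need >= {min_genes} each)"
        )
    return QuerySignature(up=up, down=down).validate_sizes(min_genes, max_genes)


def enrichment_score(
    signature: pd.Series, gene_set, weighted: bool = True
) -> float:
    """Weighted KS enrichment score of a gene set against a ranked signature.

    The signature is ranked by descending z (ties broken by gene id for
    determinism). Hits advance the running sum proportionally to |z|
    (uniformly when ``weighted`` is False), misses retreat by
    ``1/(N - n_hits)``; the score is the running-sum value of largest
    magnitude. Returns NaN when the set does not intersect the signature.
    """
    sig = signature.dropna()
    order = np.lexsort((sig.index.astype(str), -sig.to_numpy()))
    z = sig.to_numpy()[order]
    genes = sig.index.to_numpy()[order]
    hit = np.isin(genes, list(gene_set))
    n_hits = int(hit.sum())
    n = len(z)
    if n_hits == 0 or n_hits == n:
        return np.nan
    if weighted:
        w = np.abs(z[hit])
        total = w.sum()
        if total == 0:
            w = np.ones(n_hits)
            total = float(n_hits)
        hit_incr = w / total
    else:
        hit_incr = np.full(n_hits, 1.0 / n_hits)
    steps = np.full(n, -1.0 / (n - n_hits))
    steps[hit] = hit_incr
    running = np.cumsum(steps)
    return float(running[np.argmax(np.abs(running))])


def wtcs(query: QuerySignature, signature: pd.Series, weighted: bool = True) -> float:
    """Weighted two-sided connectivity score on [-1, 1].

    ``(ES_up - ES_down)/2`` when the two enrichment scores disagree in
    sign, else 0. A query with only one usable side scores with that side
    alone; a query with no genes in the signature space returns NaN.
    """
    es_up = enrichment_score(signature, query.up, weighted) if query.up else np.nan
    es_dn = enrichment_score(signature, query.down, weighted) if query.down else np.nan
    up_ok, dn_ok = np.isfinite(es_up), np.isfinite(es_dn)
    if up_ok and dn_ok:
        if np.sign(es_up) == np.sign(es_dn):
            return 0.0
        return float((es_up - es_dn) / 2.0)
    if up_ok:
        return float(es_up)
    if dn_ok:
        return float(-es_dn)
    log.warning("wtcs: query has no genes in the signature space")
    return np.nan


def normalize_scores(
    scores: pd.Series, groups: pd.Series | pd.DataFrame
) -> pd.Series:
    """Normalize raw connectivity scores within signature groups.

    ``ncs = wtcs / mean(|wtcs| over same-sign scores of the same group)``.
    Zero scores stay zero; a score whose group holds no other same-sign
    member normalizes against itself (ncs = +/-1).
    """
    if isinstance(groups, pd.DataFrame):
        keys = groups.astype(str).agg("|".join, axis=1)
    else:
        keys = groups.astype(str)
    keys = keys.reindex(scores.index)
    out = pd.Series(np.nan, index=scores.index, dtype=float)
    for _, idx in keys.groupby(keys).groups.items():
        w = scores.loc[idx]
        pos = w[w > 0]
        neg = w[w < 0]
        res = pd.Series(0.0, index=w.index)
        if len(pos):
            res[pos.index] = pos / pos.abs().mean()
        if len(neg):
            res[neg.index] = neg / neg.abs().mean()
        res[w.isna()] = np.nan
        out.loc[idx] = res
    return out


def tau(ncs_query: float, touchstone_ncs) -> float:
    """Signed percentile of |NCS| against a touchstone distribution.

    ``sign(ncs) * 100 * (fraction of touchstone |ncs| strictly below
    |ncs_query|)``; range [-100, 100], 0 for a zero score.
    """
    ref = np.asarray(touchstone_ncs, dtype=float)
    ref = ref[np.isfinite(ref)]
    if len(ref) == 0:
        raise ValueError("empty touchstone distribution")
    if not np.isfinite(ncs_query):
        return np.nan
    if ncs_query == 0:
        return 0.0
    frac = np.mean(np.abs(ref) < abs(ncs_query))
    return float(np.sign(ncs_query) * 100.0 * frac)


@dataclass
class QueryResult:
    """Per-signature connectivity table plus the per-perturbagen summary."""

    results: pd.DataFrame
    summary: pd.DataFrame = field(default_factory=pd.DataFrame)


def run_query(
    query: QuerySignature,
    reference: ExpressionMatrix,
    query_id: str = "query",
    touchstone_types=DEFAULT_TOUCHSTONE_TYPES,
    weighted: bool = True,
) -> pd.DataFrame:
    """Score a query against every signature of a level-5 collection.

    ``reference.col_meta`` must carry ``pert_id``, ``pert_type``, ``cell_id``
    and optionally ``pert_dose``/``pert_time``. NCS normalization groups are
    (cell_id, pert_type); the tau reference for each cell line is the NCS of
    that cell line's touchstone-eligible signatures (``touchstone_types``).
    """
    meta = reference.col_meta
    for col in ("pert_id", "pert_type", "cell_id"):
        if col not in meta.columns:
            raise ValueError(f"reference col_meta lacks required column {col!r}")
    raw = pd.Series(
        {
            sid: wtcs(query, reference.values[sid], weighted=weighted)
            for sid in reference.values.columns
        },
        name="wtcs",
    )
    ncs = normalize_scores(raw, meta[["cell_id", "pert_type"]])
    taus = pd.Series(np.nan, index=raw.index, dtype=float)
    for cell, idx in meta.groupby("cell_id").groups.items():
        eligible = meta.loc[idx, "pert_type"].isin(touchstone_types)
        ref_ncs = ncs.loc[idx][eligible.to_numpy()]
        if len(ref_ncs.dropna()) == 0:
            ref_ncs = ncs.loc[idx]
        for sid in idx:
            if np.isfinite(ncs[sid]):
                taus[sid] = tau(ncs[sid], ref_ncs)
    out = pd.DataFrame(
        {
            "query_id": query_id,
            "pert_id": meta["pert_id"],
            "pert_type": meta["pert_type"],
            "cell_id": meta["cell_id"],
            "pert_idose": meta.get("pert_dose", pd.Series("", index=meta.index)),
            "pert_itime": meta.get("pert_time", pd.Series("", index=meta.index)),
            "wtcs": raw,
            "ncs": ncs,
            "tau": taus,
        }
    )
    out.index.name = "signature_id"
    return out


def summarize_median_tau(
    results: pd.DataFrame, pert_types=("CP",), top_k: int = 25
) -> QueryResult:
    """Aggregate per-signature taus to per-perturbagen median tau.

    Within each cell line a perturbagen is represented by its strongest
    signature (max |NCS|, typically the most responsive dose); the summary
    tau is the median of these per-cell-line taus. ``median_tau > 0`` marks
    a mimic of the query, ``< 0`` a reverser. ``top_k`` rows from each end
    of the descending ranking give the mimic/reverse shortlists.
    """
    df = results[results["pert_type"].isin(pert_types)].copy()
    records = []
    for pert, sub in df.groupby("pert_id"):
        cell_taus = {}
        for cell, cs in sub.groupby("cell_id"):
            cs = cs.dropna(subset=["tau"])
            if cs.empty:
                continue
            best = cs.loc[cs["ncs"].abs().idxmax()]
            cell_taus[cell] = float(best["tau"])
        if not cell_taus:
            continue
        med = float(np.median(list(cell_taus.values())))
        records.append(
            {
                "pert_id": pert,
                "n_cell_lines": len(cell_taus),
                "median_tau": med,
                "classification": "mimic" if med > 0 else ("reverse" if med < 0 else "null"),
            }
        )
    summary = pd.DataFrame(records)
    if not summary.empty:
        summary = summary.sort_values(
            ["median_tau", "pert_id"], ascending=[False, True]
        ).reset_index(drop=True)
    if top_k > len(summary):
        log.warning(
            "summarize_median_tau: top_k=%d exceeds %d perturbagens; full list returned",
            top_k, len(summary),
        )
    return QueryResult(results=results, summary=summary)


def query_from_signature(
    signature: pd.Series, n_up: int = 50, n_down: int = 50
) -> QuerySignature:
    """Query built from a signature's own extreme genes (top/bottom z).

    List sizes are capped at half the signature's gene space so the two
    tails never overlap.
    """
    sig = signature.dropna()
    cap = len(sig) // 2
    n_up, n_down = min(n_up, cap), min(n_down, cap)
    order = np.lexsort((sig.index.astype(str), -sig.to_numpy()))
    genes = sig.index.to_numpy()[order]
    return QuerySignature(up=tuple(genes[:n_up]), down=tuple(genes[-n_down:]))


def touchstone_similarity(
    reference: ExpressionMatrix,
    pert_id: str,
    cell_id: str | None = None,
    pert_dose: str | None = None,
    pert_time: str | None = None,
    n_up: int = 50,
    n_down: int = 50,
    method: str = "query",
) -> pd.DataFrame:
    """Rank all reference signatures by similarity to a selected signature.

    The selected perturbagen (optionally narrowed by cell line, dose, time)
    seeds either a query built from its own extreme genes (``method =
    "query"``, scored via WTCS/NCS/tau) or a direct signature-to-signature
    Spearman ranking (``method = "correlation"``). KD/OE reference classes
    participate, so shared-mechanism genetic perturbagens surface. Ties are
    broken lexicographically by pert_id.
    """
    meta = reference.col_meta
    mask = meta["pert_id"].astype(str) == str(pert_id)
    if cell_id is not None:
        mask &= meta["cell_id"].astype(str) == str(cell_id)
    if pert_dose is not None and "pert_dose" in meta.columns:
        mask &= meta["pert_dose"].astype(str) == str(pert_dose)
    if pert_time is not None and "pert_time" in meta.columns:
        mask &= meta["pert_time"].astype(str) == str(pert_time)
    matches = meta.index[mask]
    if len(matches) == 0:
        raise ValueError(
            f"no signature matches pert_id={pert_id!r}, cell_id={cell_id!r}, "
            f"dose={pert_dose!r}, time={pert_time!r}"
        )
    selected = sorted(matches)[0]
    if len(matches) > 1:
        log.info(
            "touchstone_similarity: %d signatures match; using %s",
            len(matches), selected,
        )
    if method == "query":
        q = query_from_signature(reference.values[selected], n_up=n_up, n_down=n_down)
        res = run_query(q, reference, query_id=f"touchstone:{selected}")
        res["score"] = res["tau"]
        secondary = res["ncs"]
    elif method == "correlation":
        corr = spearman_cross(
            reference.values[[selected]].to_numpy(), reference.values.to_numpy()
        )[0]
        res = pd.DataFrame(
            {
                "query_id": f"touchstone:{selected}",
                "pert_id": meta["pert_id"],
                "pert_type": meta["pert_type"],
                "cell_id": meta["cell_id"],
                "pert_idose": meta.get("pert_dose", pd.Series("", index=meta.index)),
                "pert_itime": meta.get("pert_time", pd.Series("", index=meta.index)),
                "score": corr,
            },
            index=meta.index,
        )
        secondary = res["score"]
    else:
        raise ValueError(f"unknown method {method!r}")
    res = res.assign(_secondary=secondary)
    res["pc_selection"] = selected
    res = res.sort_values(
        ["score", "_secondary", "pert_id"], ascending=[False, False, True],
        kind="mergesort",
    ).drop(columns="_secondary")
    res["rank"] = np.arange(1, len(res) + 1)
    return res
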