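"""Independent brute-force reference implementations.

Everything here is written from the definitions using plain loops (or raw
numpy sorting), deliberately avoiding the code paths of the package, so
the two routes can be compared on randomized instances.
"""

from __future__ import annotations

import math

import numpy as np


def median_oracle(values) -> float:
    v = sorted(float(x) for x in values)
    n = len(v)
    if n % 2:
        return v[n // 2]
    return 0.5 * (v[n // 2 - 1] + v[n // 2])


def ranks_oracle(values) -> list[float]:
    """Average-tie ranks (1-based) via explicit grouping."""
    v = list(map(float, values))
    order = sorted(range(len(v)), key=lambda i: v[i])
    ranks = [0.0] * len(v)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and v[order[j + 1]] == v[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def pearson_oracle(x, y) -> float:
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    dx = math.sqrt(sum((a - mx) ** 2 for a in x))
    dy = math.sqrt(sum((b - my) ** 2 for b in y))
    return num / (dx * dy)


def spearman_oracle(x, y) -> float:
    return pearson_oracle(ranks_oracle(x), ranks_oracle(y))


def quantile_linear_oracle(values, q: float) -> float:
    """Linear-interpolation quantile between order statistics."""
    v = sorted(map(float, values))
    h = (len(v) - 1) * q
    lo = int(math.floor(h))
    hi = min(lo + 1, len(v) - 1)
    return v[lo] + (h - lo) * (v[hi] - v[lo])


def cc_oracle(columns) -> float:
    """75th-percentile pairwise Spearman among replicate columns."""
    cols = [list(c) for c in columns]
    pairs = [
        spearman_oracle(cols[i], cols[j])
        for i in range(len(cols))
        for j in range(i + 1, len(cols))
    ]
    return quantile_linear_oracle(pairs, 0.75)


def ss_oracle(z_rows, n_replicates: int, threshold: float = 2.0) -> int:
    """z_rows: per-gene lists of replicate z-scores."""
    count = 0
    for row in z_rows:
        za = (sum(row) / len(row)) * math.sqrt(n_replicates)
        if abs(za) > threshold:
            count += 1
    return count


def quantile_normalize_oracle(matrix) -> np.ndarray:
    """Column-wise quantile normalization with mean-of-sorted target and
    mean-of-target-quantiles for ties, by explicit loops."""
    mat = np.asarray(matrix, dtype=float)
    n, m = mat.shape
    ref = np.mean(np.stack([np.sort(mat[:, j]) for j in range(m)], axis=1), axis=1)
    out = np.empty_like(mat)
    for j in range(m):
        col = mat[:, j]
        order = sorted(range(n), key=lambda i: col[i])
        assigned = [0.0] * n
        i = 0
        while i < n:
            k = i
            while k + 1 < n and col[order[k + 1]] == col[order[i]]:
                k += 1
            mean_target = sum(ref[i : k + 1]) / (k - i + 1)
            for t in range(i, k + 1):
                assigned[order[t]] = mean_target
            i = k + 1
        out[:, j] = assigned
    return out


def robust_z_oracle(matrix) -> np.ndarray:
    """Gene-wise robust z against all columns, loops only."""
    mat = np.asarray(matrix, dtype=float)
    out = np.empty_like(mat)
    for g in range(mat.shape[0]):
        row = list(mat[g])
        med = median_oracle(row)
        mad = median_oracle([abs(x - med) for x in row])
        if max(row) == min(row):
            out[g] = 0.0
        else:
            out[g] = [(x - med) / (1.4826 * max(mad, 1e-6)) for x in row]
    return out


def wtcs_oracle(up, down, gene_z: dict) -> float:
    """Two-sided weighted KS score by explicit running-sum enumeration."""

    def es(gene_set):
        items = sorted(gene_z.items(), key=lambda kv: (-kv[1], kv[0]))
        hits = [g for g, _ in items if g in gene_set]
        if not hits or len(hits) == len(items):
            return float("nan")
        total_w = sum(abs(z) for g, z in items if g in gene_set)
        n_miss = len(items) - len(hits)
        running, best = 0.0, 0.0
        for g, z in items:
            if g in gene_set:
                running += abs(z) / total_w if total_w > 0 else 1.0 / len(hits)
            else:
                running -= 1.0 / n_miss
            if abs(running) > abs(best):
                best = running
        return best

    es_up = es(set(up))
    es_dn = es(set(down))
    if math.copysign(1, es_up) == math.copysign(1, es_dn):
        return 0.0
    return (es_up - es_dn) / 2.0


def tau_oracle(ncs_query: float, touchstone) -> float:
    if ncs_query == 0:
        return 0.0
    count = sum(1 for t in touchstone if abs(t) < abs(ncs_query))
    sign = 1.0 if ncs_query > 0 else -1.0
    return sign * 100.0 * count / len(touchstone)


def recall_fraction_oracle(rank_pcts, threshold: float) -> float:
    passed = sum(1 for r in rank_pcts if r < threshold)
    return passed / len(rank_pcts)
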