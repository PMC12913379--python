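"""TAS-scaled 2-D embedding of signature collections.

Signatures (level-5 z-score vectors) are projected to two dimensions with
t-SNE so that compound/cell-line/dose response structure can be inspected,
with each point's transcriptional activity score carried alongside for
size-scaled plotting.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.manifold import TSNE

from .core import ExpressionMatrix


def embed_signatures(
    level5: ExpressionMatrix,
    metrics: pd.DataFrame | None = None,
    seed: int = 0,
    perplexity: float | None = None,
) -> pd.DataFrame:
    """Deterministic 2-D t-SNE coordinates for each signature.

    Parameters
    ----------
    level5
        Signature matrix (genes x signatures), at least 5 signatures.
    metrics
        Optional per-signature table indexed like the signature columns;
        its ``tas`` column (and pert/cell metadata) is carried into the
        output for size-scaled plotting.
    perplexity
        Defaults to ``min(30, (n - 1) / 3)``.
    """
    n = level5.n_samples
    if n < 5:
        raise ValueError(f"need at least 5 signatures to embed, got {n}")
    x = level5.values.T.to_numpy()
    x = np.nan_to_num(x, nan=0.0)
    if perplexity is None:
        perplexity = min(30.0, (n - 1) / 3.0)
    coords = TSNE(
        n_components=2,
        perplexity=perplexity,
        random_state=seed,
        init="pca",
        learning_rate="auto",
    ).fit_transform(x)
    out = pd.DataFrame(
        coords, columns=["x", "y"], index=level5.values.columns
    )
    out.index.name = "signature_id"
    carry = level5.col_meta[
        [c for c in ("pert_id", "cell_id", "pert_dose", "pert_time")
         if c in level5.col_meta.columns]
    ]
    out = out.join(carry)
    if metrics is not None and "tas" in metrics.columns:
        out["tas"] = metrics["tas"].reindex(out.index)
    return out
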