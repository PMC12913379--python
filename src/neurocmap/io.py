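"""Readers and writers: GCT 1.3 matrices, metadata TSVs, DEG tables.

The GCT dialect is the text ``#1.3`` format with multi-row/column metadata
blocks, tab delimited, ``NaN`` for missing numeric cells and empty strings
for the unused corner cells of the column-metadata block.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .core import ExpressionMatrix, _require_columns

log = logging.getLogger(__name__)


class GctFormatError(ValueError):
    """Raised when a file does not conform to the GCT 1.3 dialect."""


def read_gct(path: str | Path, level: int | None = None) -> ExpressionMatrix:
    """Read a GCT 1.3 text matrix.

    Parameters
    ----------
    path
        File starting with a ``#1.3`` version line and a four-field
        dimension line ``nrows\\tncols\\tnrowmeta\\tncolmeta``.
    level
        Optional processing level to tag the matrix with.
    """
    path = Path(path)
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or lines[0].strip() != "#1.3":
        got = lines[0] if lines else "<empty file>"
        raise GctFormatError(f"{path}: expected '#1.3' version line, got {got!r}")
    dims = lines[1].split("\t")
    if len(dims) != 4:
        raise GctFormatError(f"{path}: malformed dimension line {lines[1]!r}")
    try:
        n_rows, n_cols, n_rmeta, n_cmeta = (int(d) for d in dims)
    except ValueError as e:
        raise GctFormatError(f"{path}: non-integer dimension line {lines[1]!r}") from e

    expected = 3 + n_cmeta + n_rows
    if len(lines) < expected:
        raise GctFormatError(
            f"{path}: dimension line promises {expected} lines, file has {len(lines)}"
        )

    header = lines[2].split("\t")
    if len(header) != 1 + n_rmeta + n_cols:
        raise GctFormatError(
            f"{path}: header has {len(header)} fields, expected {1 + n_rmeta + n_cols}"
        )
    rmeta_names = header[1 : 1 + n_rmeta]
    sample_ids = header[1 + n_rmeta :]

    cmeta_rows = {}
    for i in range(n_cmeta):
        fields = lines[3 + i].split("\t")
        if len(fields) != 1 + n_rmeta + n_cols:
            raise GctFormatError(
                f"{path}: column-metadata line {3 + i + 1} has {len(fields)} fields"
            )
        cmeta_rows[fields[0]] = fields[1 + n_rmeta :]

    gene_ids: list[str] = []
    rmeta_data: list[list[str]] = []
    data = np.empty((n_rows, n_cols), dtype=float)
    for r in range(n_rows):
        fields = lines[3 + n_cmeta + r].split("\t")
        if len(fields) != 1 + n_rmeta + n_cols:
            raise GctFormatError(
                f"{path}: data line {3 + n_cmeta + r + 1} has {len(fields)} fields, "
                f"expected {1 + n_rmeta + n_cols}"
            )
        gene_ids.append(fields[0])
        rmeta_data.append(fields[1 : 1 + n_rmeta])
        data[r] = [float(x) if x != "" else np.nan for x in fields[1 + n_rmeta :]]

    values = pd.DataFrame(data, index=pd.Index(gene_ids, name="id"), columns=sample_ids)
    row_meta = pd.DataFrame(
        rmeta_data, index=values.index, columns=rmeta_names, dtype=str
    )
    col_meta = pd.DataFrame(cmeta_rows, index=pd.Index(sample_ids, name="id"), dtype=str)
    return ExpressionMatrix(values=values, row_meta=row_meta, col_meta=col_meta, level=level)


def _fmt(x: float) -> str:
    if np.isnan(x):
        return "NaN"
    return repr(float(x))


def write_gct(matrix: ExpressionMatrix, path: str | Path) -> Path:
    """Write a GCT 1.3 text file; numeric cells at full precision.

    Column order follows ``matrix.values.columns``; metadata fields are
    serialized as strings.
    """
    path = Path(path)
    v = matrix.values
    rm = matrix.row_meta.astype(str)
    cm = matrix.col_meta.astype(str)
    n_rows, n_cols = v.shape
    n_rmeta, n_cmeta = rm.shape[1], cm.shape[1]
    out = ["#1.3", f"{n_rows}\t{n_cols}\t{n_rmeta}\t{n_cmeta}"]
    out.append("\t".join(["id", *rm.columns.astype(str), *v.columns.astype(str)]))
    for name in cm.columns:
        out.append("\t".join([str(name), *[""] * n_rmeta, *cm[name].tolist()]))
    arr = v.to_numpy()
    for r in range(n_rows):
        cells = [_fmt(x) for x in arr[r]]
        out.append("\t".join([str(v.index[r]), *rm.iloc[r].tolist(), *cells]))
    path.write_text("\n".join(out) + "\n")
    return path


def read_probe_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV probe-annotation table (gene_id, gene_symbol, bead_barcode,
    invariant_level, panel)."""
    from .core import PROBE_COLUMNS, validate_panel

    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, PROBE_COLUMNS, f"probe table {path}")
    df["invariant_level"] = df["invariant_level"].astype(int)
    return validate_panel(df)


def read_sample_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV sample-metadata table."""
    from .core import SAMPLE_COLUMNS

    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, SAMPLE_COLUMNS, f"sample table {path}")
    return df


def read_deg_table(
    path: str | Path,
    id_column: str = "gene_id",
    lfc_column: str = "log2_fold_change",
    sig_column: str | None = "fdr",
    id_map: pd.DataFrame | None = None,
    sep: str | None = None,
) -> pd.DataFrame:
    """Read a differential-expression table into the canonical DEG layout.

    Returns a DataFrame with columns ``gene_id`` (upper-cased symbols),
    ``log2_fold_change`` and, when ``sig_column`` is given, ``significance``.

    Parameters
    ----------
    id_map
        Optional two-column mapping (source id -> symbol), e.g. Ensembl to
        HGNC; rows whose id is absent from the map are dropped and counted.
        No network lookups are ever performed.

    Notes
    -----
    Duplicated gene ids are resolved by keeping the row with the largest
    ``|log2FC|``; all drops are logged.
    """
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    for col in [id_column, lfc_column] + ([sig_column] if sig_column else []):
        if col not in df.columns:
            raise ValueError(
                f"column {col!r} not in {path}; available: {list(df.columns)}"
            )
    out = pd.DataFrame(
        {
            "gene_id": df[id_column].astype(str),
            "log2_fold_change": pd.to_numeric(df[lfc_column], errors="coerce"),
        }
    )
    if sig_column:
        out["significance"] = pd.to_numeric(df[sig_column], errors="coerce")

    n0 = len(out)
    if id_map is not None:
        key, val = id_map.columns[:2]
        mapping = dict(zip(id_map[key].astype(str), id_map[val].astype(str)))
        out["gene_id"] = out["gene_id"].map(mapping)
        unmapped = out["gene_id"].isna().sum()
        if unmapped:
            log.info("read_deg_table: dropped %d unmappable gene ids", unmapped)
        out = out.dropna(subset=["gene_id"])
    out["gene_id"] = out["gene_id"].str.upper()
    out = out[np.isfinite(out["log2_fold_change"])]

    # duplicate resolution: keep the row with the strongest fold change
    order = out["log2_fold_change"].abs().sort_values(ascending=False).index
    out = out.loc[order].drop_duplicates(subset="gene_id", keep="first")
    n_dropped = n0 - len(out)
    if n_dropped:
        log.info("read_deg_table: %d of %d rows dropped (unmappable/duplicate/non-finite)", n_dropped, n0)
    out.attrs["n_dropped"] = int(n_dropped)
    return out.reset_index(drop=True)
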