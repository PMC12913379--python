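"""Core domain types.

The toolkit is DataFrame-centric: probe panels, sample metadata and
differential-expression tables are plain :class:`pandas.DataFrame` objects
with documented column contracts, while expression data at any processing
level travels as an :class:`ExpressionMatrix` (genes x samples values plus
aligned row/column metadata, tagged with its level 1-5).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

#: Number of disease-relevant (non-invariant) probes in the neuronal panel.
PANEL_SIZE = 467

#: Perturbagen classes: compound, vehicle control, knockdown, overexpression.
PERT_TYPES = ("CP", "CTRL", "KD", "OE")

#: Number of invariant-ladder expression levels used for per-well calibration.
N_INVARIANT_LEVELS = 10

# Column contracts -----------------------------------------------------------

#: Required columns of a probe panel table (one row per bead barcode).
PROBE_COLUMNS = ("gene_id", "gene_symbol", "bead_barcode", "invariant_level", "panel")

#: Required columns of a sample metadata table (one row per profiled well).
SAMPLE_COLUMNS = (
    "sample_id",
    "plate_id",
    "well",
    "pert_id",
    "pert_type",
    "pert_dose",
    "pert_time",
    "cell_id",
)


@dataclass(frozen=True)
class GeneProbe:
    """One bead barcode coupled to one gene.

    ``invariant_level`` is 0 for ordinary panel probes and 1-10 for probes on
    the invariant calibration ladder (level 10 = highest expression).
    """

    gene_id: str
    gene_symbol: str
    bead_barcode: str
    invariant_level: int = 0
    panel: str = "neuro467"

    def __post_init__(self) -> None:
        if not 0 <= int(self.invariant_level) <= N_INVARIANT_LEVELS:
            raise ValueError(
                f"invariant_level must be 0..{N_INVARIANT_LEVELS}, "
                f"got {self.invariant_level}"
            )


@dataclass(frozen=True)
class SampleRecord:
    """Metadata for one profiled well."""

    sample_id: str
    plate_id: str
    well: str
    pert_id: str
    pert_type: str
    pert_dose: str
    pert_time: str
    cell_id: str

    def __post_init__(self) -> None:
        if self.pert_type not in PERT_TYPES:
            raise ValueError(
                f"pert_type must be one of {PERT_TYPES}, got {self.pert_type!r}"
            )

    @property
    def replicate_group(self) -> str:
        return replicate_group_key(
            self.pert_id, self.cell_id, self.pert_dose, self.pert_time
        )


_QUANTITY_RE = re.compile(r"^\s*([-+]?\d*\.?\d+(?:[eE][-+]?\d+)?)\s*([^\s]*)\s*$")


def parse_quantity(text: str) -> tuple[float, str]:
    """Parse a dose/time string like ``"0.5 uM"`` into ``(0.5, "uM")``.

    The verbatim string is kept in metadata tables; comparisons and filters
    use the parsed pair.
    """
    m = _QUANTITY_RE.match(str(text))
    if m is None:
        raise ValueError(f"cannot parse quantity {text!r}")
    return float(m.group(1)), m.group(2)


def replicate_group_key(
    pert_id: str, cell_id: str, pert_dose: str, pert_time: str
) -> str:
    """Deterministic replicate-group key: pure function of its components."""
    return f"{pert_id}:{cell_id}:{pert_dose}:{pert_time}"


def replicate_groups(samples: pd.DataFrame) -> pd.Series:
    """Replicate-group key per sample, indexed by ``sample_id``.

    Wells sharing (pert_id, cell_id, dose, time) are biological replicates
    and are collapsed into a single level-5 signature.
    """
    _require_columns(samples, SAMPLE_COLUMNS, "sample table")
    keys = (
        samples["pert_id"].astype(str)
        + ":"
        + samples["cell_id"].astype(str)
        + ":"
        + samples["pert_dose"].astype(str)
        + ":"
        + samples["pert_time"].astype(str)
    )
    return pd.Series(keys.to_numpy(), index=samples["sample_id"].to_numpy(), name="replicate_group")


def validate_panel(panel: pd.DataFrame) -> pd.DataFrame:
    """Validate a probe panel table and return it.

    Enforces the 1:1 barcode-to-gene coupling and, when invariant probes are
    present, that they cover at least two ladder levels.
    """
    _require_columns(panel, PROBE_COLUMNS, "probe panel")
    dup = panel["bead_barcode"][panel["bead_barcode"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate bead barcodes in panel: {sorted(set(dup))[:5]}")
    dupg = panel["gene_id"][panel["gene_id"].duplicated()]
    if len(dupg):
        raise ValueError(f"genes mapped by multiple barcodes: {sorted(set(dupg))[:5]}")
    lev = panel["invariant_level"].astype(int)
    if (lev < 0).any() or (lev > N_INVARIANT_LEVELS).any():
        raise ValueError("invariant_level outside 0..10")
    return panel


def panel_genes(panel: pd.DataFrame, invariant: bool | None = None) -> pd.Index:
    """Gene ids in a panel; ``invariant`` selects ladder (True) or ordinary
    (False) probes, None selects all."""
    lev = panel["invariant_level"].astype(int)
    if invariant is None:
        mask = np.ones(len(panel), dtype=bool)
    elif invariant:
        mask = (lev > 0).to_numpy()
    else:
        mask = (lev == 0).to_numpy()
    return pd.Index(panel.loc[mask, "gene_id"].astype(str))


@dataclass
class ExpressionMatrix:
    """A genes x samples matrix with aligned metadata and a processing level.

    Parameters
    ----------
    values
        Numeric DataFrame; index = gene/probe ids, columns = sample ids.
    row_meta
        Per-gene metadata, indexed like ``values.index`` (may be empty).
    col_meta
        Per-sample metadata, indexed like ``values.columns`` (may be empty).
    level
        Processing level 1-5; levels 4-5 hold unitless robust z-scores,
        levels 2-3 nonnegative fluorescence-scale values.
    """

    values: pd.DataFrame
    row_meta: pd.DataFrame = field(default_factory=pd.DataFrame)
    col_meta: pd.DataFrame = field(default_factory=pd.DataFrame)
    level: int | None = None

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        if self.row_meta is None or len(self.row_meta.columns) == 0:
            self.row_meta = pd.DataFrame(index=self.values.index)
        if self.col_meta is None or len(self.col_meta.columns) == 0:
            self.col_meta = pd.DataFrame(index=self.values.columns)
        if not self.row_meta.index.equals(self.values.index):
            if len(self.row_meta) != len(self.values):
                raise ValueError(
                    f"row_meta has {len(self.row_meta)} rows for "
                    f"{len(self.values)} genes"
                )
            self.row_meta = self.row_meta.set_axis(self.values.index)
        if not self.col_meta.index.equals(self.values.columns):
            if len(self.col_meta) != self.values.shape[1]:
                raise ValueError(
                    f"col_meta has {len(self.col_meta)} rows for "
                    f"{self.values.shape[1]} samples"
                )
            self.col_meta = self.col_meta.set_axis(self.values.columns)
        if self.level is not None and not 1 <= int(self.level) <= 5:
            raise ValueError(f"level must be 1..5, got {self.level}")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset(
        self,
        genes: Iterable[str] | None = None,
        samples: Iterable[str] | None = None,
    ) -> "ExpressionMatrix":
        """Row/column subset preserving metadata alignment."""
        v = self.values
        if genes is not None:
            genes = [g for g in genes if g in v.index]
            v = v.loc[genes]
        if samples is not None:
            samples = [s for s in samples if s in v.columns]
            v = v[samples]
        return ExpressionMatrix(
            values=v,
            row_meta=self.row_meta.loc[v.index],
            col_meta=self.col_meta.loc[v.columns],
            level=self.level,
        )

    def with_level(self, level: int) -> "ExpressionMatrix":
        return ExpressionMatrix(
            values=self.values, row_meta=self.row_meta, col_meta=self.col_meta,
            level=level,
        )


def _require_columns(df: pd.DataFrame, cols: Iterable[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(
            f"{what} is missing columns {missing}; available: {list(df.columns)}"
        )
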