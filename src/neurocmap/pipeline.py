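"""End-to-end orchestration: bead table -> levels 2-5 -> QC metrics.

``process_screen`` chains the five processing levels, dropping wells that
fail invariant-ladder QC and excluding the calibration probes themselves
from the z-score space (they are pinned to the ladder by construction and
carry no biological signal). Robust z-scores are computed on the
log2(x + 1) scale of the quantile-normalized data.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import ExpressionMatrix, replicate_groups
from .io import write_gct
from .levels import (
    collapse_all,
    invariant_normalize,
    level1_to_level2,
    quantile_normalize,
    robust_zscore,
)
from .metrics import compute_signature_metrics

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Resolved options of one processing/query run; serializes to JSON."""

    plate_column: str = "plate_id"
    za_mode: str = "sqrt_n_mean"
    tas_mode: str = "sqrt"
    log2_before_zscore: bool = True
    n_up: int = 137
    n_down: int = 150
    min_query_genes: int = 10
    max_query_genes: int = 150
    top_k: int = 25
    tas_threshold: float = 0.212
    recall_pass_threshold_pct: float = 5.0
    seed: int = 0

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1) + "\n")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class ProcessResult:
    """All artifacts of one screen-processing run."""

    level2: ExpressionMatrix
    level3: ExpressionMatrix
    level4: ExpressionMatrix
    level5: ExpressionMatrix
    metrics: pd.DataFrame
    well_qc: pd.DataFrame
    collapse_weights: pd.DataFrame
    config: RunConfig = field(default_factory=RunConfig)

    def write(self, outdir) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for lvl, m in (
            (2, self.level2), (3, self.level3), (4, self.level4), (5, self.level5)
        ):
            write_gct(m, outdir / f"level{lvl}.gct")
        self.metrics.to_csv(outdir / "signature_metrics.tsv", sep="\t")
        self.well_qc.to_csv(outdir / "well_qc.tsv", sep="\t")
        self.collapse_weights.to_csv(outdir / "collapse_weights.tsv", sep="\t", index=False)
        self.config.to_json(outdir / "run_config.json")
        return outdir


def process_screen(
    beads: pd.DataFrame,
    samples: pd.DataFrame,
    panel: pd.DataFrame,
    config: RunConfig | None = None,
    invariant_reference: pd.Series | None = None,
) -> ProcessResult:
    """Run the full five-level pipeline on a bead-level screen.

    Parameters
    ----------
    beads
        Bead table (plate_id, well, bead_barcode, fluorescence_intensity).
    samples
        Sample metadata; ``sample_id`` must equal ``plate_id:well``.
    panel
        Probe annotation table including the invariant ladder.
    """
    if config is None:
        config = RunConfig()
    level2 = level1_to_level2(beads, panel)

    meta = samples.set_index("sample_id")
    missing = [s for s in level2.values.columns if s not in meta.index]
    if missing:
        raise ValueError(f"samples without metadata: {missing[:5]}")
    level2.col_meta = meta.loc[level2.values.columns]

    cal = invariant_normalize(level2, reference=invariant_reference)
    failed = cal.well_qc.index[~cal.well_qc["passed"]].tolist()
    if failed:
        log.warning("process_screen: excluding %d wells failing ladder QC", len(failed))
    keep = [s for s in cal.matrix.values.columns if s not in set(failed)]
    calibrated = cal.matrix.subset(samples=keep)

    level3 = quantile_normalize(
        calibrated, calibrated.col_meta[config.plate_column]
    )

    ordinary = level3.row_meta.index[
        level3.row_meta["invariant_level"].astype(int) == 0
    ]
    z_input = level3.subset(genes=ordinary)
    if config.log2_before_zscore:
        z_input = ExpressionMatrix(
            values=np.log2(z_input.values + 1.0),
            row_meta=z_input.row_meta,
            col_meta=z_input.col_meta,
            level=3,
        )
    level4 = robust_zscore(z_input, z_input.col_meta[config.plate_column])

    groups = replicate_groups(samples[samples["sample_id"].isin(keep)])
    level5, weights = collapse_all(level4, groups)
    metrics = compute_signature_metrics(
        level4, groups, za_mode=config.za_mode, tas_mode=config.tas_mode
    )
    metrics = metrics.join(
        level5.col_meta[
            [c for c in ("pert_id", "pert_type", "cell_id", "pert_dose", "pert_time")
             if c in level5.col_meta.columns]
        ]
    )
    log.info(
        "process_screen: %d wells -> %d signatures (%d wells excluded)",
        len(level2.values.columns), level5.n_samples, len(failed),
    )
    return ProcessResult(
        level2=level2,
        level3=level3,
        level4=level4,
        level5=level5,
        metrics=metrics,
        well_qc=cal.well_qc,
        collapse_weights=weights,
        config=config,
    )
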