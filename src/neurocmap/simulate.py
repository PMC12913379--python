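"""Generative simulator for bead-level screens with known ground truth.

The simulator emulates a chemical-genetic screen in neuronal cultures: a
panel of 467 disease-relevant probes plus an 80-probe invariant calibration
ladder (10 expression levels x 8 probes), profiled across cell lines,
compounds, doses and replicates on 384-well detection plates. Every data
artifact the processing pipeline consumes (bead-level fluorescence, sample
metadata, probe annotations) is emitted together with the generating truth,
so planted effects can be checked end to end.

Generative model (log2 fluorescence scale) for gene g in well w:

    log2 FI_bead = a_w * (b_g + c_{g,cell(w)} + e_{g,w} + eps_{g,w}) + d_w
                   + eta_bead

where ``b_g`` is the gene baseline, ``c`` a per-cell-line offset (zero for
invariant probes), ``e`` the planted compound effect (zero in vehicle
wells), ``eps`` well-level noise, ``(a_w, d_w)`` a monotone affine well
distortion that the invariant-ladder calibration must undo, and ``eta`` the
bead-level noise. Planted effects are specified in z-units and converted to
log2 shifts by the expected per-gene dispersion, so an "effect of 4 z"
should land near z = 4 after processing.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd

from .core import PANEL_SIZE, N_INVARIANT_LEVELS

PLATE_CAPACITY = 384
_WELL_ROWS = "ABCDEFGHIJKLMNOP"


@dataclass(frozen=True)
class ScreenConfig:
    """Study-scale parameters of a simulated screen.

    Defaults describe the reference screen used throughout the tests: six
    patient-derived cell lines exposed to 60 compounds at two doses for one
    time point in triplicate, with half the compounds transcriptionally
    active on 20-gene modules at 3-5 z.
    """

    n_cell_lines: int = 6
    n_compounds: int = 60
    doses: tuple[str, ...] = ("0.5 uM", "5 uM")
    pert_time: str = "24 h"
    n_replicates: int = 3
    n_genes: int = PANEL_SIZE
    invariant_levels: int = N_INVARIANT_LEVELS
    invariant_per_level: int = 8
    beads_per_gene: int = 3
    vehicle_wells_per_plate: int = 8
    # noise model (log2 fluorescence units)
    bead_sd: float = 0.2
    well_sd: float = 0.1
    cell_sd: float = 0.3
    baseline_range: tuple[float, float] = (4.0, 12.0)
    distortion_slope_range: tuple[float, float] = (0.85, 1.15)
    distortion_offset_range: tuple[float, float] = (-0.5, 0.5)
    # planted biology
    frac_active: float = 0.5
    module_size: int = 20
    effect_z_range: tuple[float, float] = (3.0, 5.0)
    dose_multiplier: float = 1.5  # high dose scales the effect by 1.5x

    def wells_per_plate(self) -> int:
        return self.n_compounds * len(self.doses) + self.vehicle_wells_per_plate


def null_config(**overrides) -> ScreenConfig:
    """A no-effect screen: same layout, no active compounds."""
    return replace(ScreenConfig(frac_active=0.0), **overrides)


@dataclass
class ScreenTruth:
    """Ground truth behind one simulated screen."""

    baselines: pd.Series                       # log2 expected expression per gene
    invariant_assignment: dict[str, int]       # gene -> ladder level (0 = ordinary)
    effects: dict[str, dict]                   # pert_id -> {genes, signs, effect_z}
    cell_modifiers: pd.DataFrame               # genes x cell lines, log2 offsets
    z_unit_log2: float                         # log2 shift corresponding to 1 z
    bead_sd: float
    well_sd: float
    seed: int
    config: ScreenConfig

    def active_compounds(self) -> list[str]:
        return sorted(self.effects)

    def to_json(self, path) -> None:
        payload = {
            "baselines": self.baselines.to_dict(),
            "invariant_assignment": self.invariant_assignment,
            "effects": {
                k: {
                    "genes": list(v["genes"]),
                    "signs": {g: int(s) for g, s in v["signs"].items()},
                    "effect_z": float(v["effect_z"]),
                }
                for k, v in self.effects.items()
            },
            "z_unit_log2": self.z_unit_log2,
            "bead_sd": self.bead_sd,
            "well_sd": self.well_sd,
            "seed": self.seed,
            "config": asdict(self.config),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


@dataclass
class SimulatedScreen:
    """Bead table + sample metadata + probe panel + generating truth."""

    beads: pd.DataFrame
    samples: pd.DataFrame
    panel: pd.DataFrame
    truth: ScreenTruth


def make_panel(config: ScreenConfig) -> pd.DataFrame:
    """Probe annotation table: ordinary panel genes plus the invariant ladder."""
    rows = []
    for i in range(config.n_genes):
        rows.append(
            {
                "gene_id": f"NG{i + 1:04d}",
                "gene_symbol": f"NG{i + 1:04d}",
                "bead_barcode": f"BC{i + 1:05d}",
                "invariant_level": 0,
                "panel": "neuro467",
            }
        )
    k = config.n_genes
    for level in range(1, config.invariant_levels + 1):
        for j in range(config.invariant_per_level):
            k += 1
            rows.append(
                {
                    "gene_id": f"INV{level:02d}_{j + 1}",
                    "gene_symbol": f"INV{level:02d}_{j + 1}",
                    "bead_barcode": f"BC{k:05d}",
                    "invariant_level": level,
                    "panel": "neuro467",
                }
            )
    return pd.DataFrame(rows)


def _well_label(i: int) -> str:
    return f"{_WELL_ROWS[i // 24]}{i % 24 + 1:02d}"


def median_noise_sd(bead_sd: float, n_beads: int) -> float:
    """Approximate standard deviation of the median of ``n_beads`` normal
    bead-level measurements (asymptotic ``sigma * sqrt(pi / (2 n))``)."""
    return bead_sd * math.sqrt(math.pi / (2.0 * n_beads))


def simulate_screen(config: ScreenConfig | None = None, seed: int = 0) -> SimulatedScreen:
    """Simulate a full bead-level screen.

    One detection plate per (cell line, replicate) carries every
    compound x dose well plus vehicle-control wells. Identical (config,
    seed) pairs reproduce byte-identical tables.
    """
    if config is None:
        config = ScreenConfig()
    if config.wells_per_plate() > PLATE_CAPACITY:
        raise ValueError(
            f"layout needs {config.wells_per_plate()} wells/plate; capacity is {PLATE_CAPACITY}"
        )
    if config.invariant_levels < 2:
        raise ValueError("at least 2 invariant ladder levels are required")
    if config.vehicle_wells_per_plate < 1:
        raise ValueError("at least one vehicle well per plate is required")
    rng = np.random.default_rng(seed)
    panel = make_panel(config)
    genes = panel["gene_id"].to_numpy()
    inv_level = panel["invariant_level"].to_numpy()
    n_genes_total = len(genes)
    ordinary = genes[inv_level == 0]

    # gene baselines: ordinary genes uniform; invariant genes sit exactly on
    # the canonical ladder 2**(level + 5)
    lo, hi = config.baseline_range
    baselines = np.empty(n_genes_total)
    baselines[inv_level == 0] = rng.uniform(lo, hi, size=(inv_level == 0).sum())
    baselines[inv_level > 0] = inv_level[inv_level > 0] + 5.0
    baseline_s = pd.Series(baselines, index=genes)

    cells = [f"CL{i + 1}" for i in range(config.n_cell_lines)]
    cell_mod = rng.normal(0.0, config.cell_sd, size=(n_genes_total, len(cells)))
    cell_mod[inv_level > 0] = 0.0  # the ladder is invariant by construction
    cell_mod_df = pd.DataFrame(cell_mod, index=genes, columns=cells)

    # planted compound effects, specified in z-units
    compounds = [f"CPD{i + 1:03d}" for i in range(config.n_compounds)]
    n_active = int(round(config.frac_active * config.n_compounds))
    active = [str(c) for c in rng.choice(compounds, size=n_active, replace=False)]
    z_unit = math.sqrt(
        config.well_sd**2
        + median_noise_sd(config.bead_sd, config.beads_per_gene) ** 2
    )
    z_unit = max(z_unit, 0.1)  # planted effects stay visible in noise-free runs
    effects: dict[str, dict] = {}
    for cpd in sorted(active):
        module = [str(g) for g in rng.choice(ordinary, size=config.module_size, replace=False)]
        signs = {
            g: (1 if i < (config.module_size + 1) // 2 else -1)
            for i, g in enumerate(module)
        }
        effect_z = float(rng.uniform(*config.effect_z_range))
        effects[cpd] = {"genes": module, "signs": signs, "effect_z": effect_z}

    # plate layout
    sample_rows = []
    plates = []
    for cell in cells:
        for rep in range(1, config.n_replicates + 1):
            plate_id = f"P_{cell}_R{rep}"
            w = 0
            wells = []
            for cpd in compounds:
                for dose in config.doses:
                    wells.append((plate_id, _well_label(w), cpd, "CP", dose, cell))
                    w += 1
            for _ in range(config.vehicle_wells_per_plate):
                wells.append((plate_id, _well_label(w), "DMSO", "CTRL", "0 uM", cell))
                w += 1
            plates.append((plate_id, cell, wells))
            for plate, well, cpd, ptype, dose, cl in wells:
                sample_rows.append(
                    {
                        "sample_id": f"{plate}:{well}",
                        "plate_id": plate,
                        "well": well,
                        "pert_id": cpd,
                        "pert_type": ptype,
                        "pert_dose": dose,
                        "pert_time": config.pert_time,
                        "cell_id": cl,
                    }
                )
    samples = pd.DataFrame(sample_rows)

    gene_index = pd.Index(genes)
    dose_mult = {
        dose: (1.0 if i == 0 else config.dose_multiplier ** i)
        for i, dose in enumerate(config.doses)
    }

    bead_frames = []
    k = config.beads_per_gene
    for plate_id, cell, wells in plates:
        n_w = len(wells)
        x = np.tile(
            (baseline_s.to_numpy() + cell_mod_df[cell].to_numpy())[:, None], (1, n_w)
        )
        for j, (_, _, cpd, ptype, dose, _) in enumerate(wells):
            if ptype == "CP" and cpd in effects:
                eff = effects[cpd]
                rows_idx = gene_index.get_indexer(eff["genes"])
                signs = np.array([eff["signs"][g] for g in eff["genes"]], dtype=float)
                x[rows_idx, j] += (
                    signs * eff["effect_z"] * dose_mult[dose] * z_unit
                )
        if config.well_sd > 0:
            x = x + rng.normal(0.0, config.well_sd, size=x.shape)
        a = rng.uniform(*config.distortion_slope_range, size=n_w)
        d = rng.uniform(*config.distortion_offset_range, size=n_w)
        x = x * a[None, :] + d[None, :]
        log_fi = np.repeat(x[:, :, None], k, axis=2)
        if config.bead_sd > 0:
            log_fi = log_fi + rng.normal(0.0, config.bead_sd, size=log_fi.shape)
        fi = np.exp2(log_fi).reshape(n_genes_total, n_w * k)
        well_labels = [w for _, w, *_ in wells]
        bead_frames.append(
            pd.DataFrame(
                {
                    "plate_id": pd.Categorical([plate_id] * (n_genes_total * n_w * k)),
                    "well": pd.Categorical(
                        np.tile(np.repeat(well_labels, k), n_genes_total)
                    ),
                    "bead_barcode": pd.Categorical(
                        np.repeat(panel["bead_barcode"].to_numpy(), n_w * k)
                    ),
                    "fluorescence_intensity": fi.ravel(),
                }
            )
        )
    beads = pd.concat(bead_frames, ignore_index=True)
    truth = ScreenTruth(
        baselines=baseline_s,
        invariant_assignment=dict(zip(genes, (int(v) for v in inv_level))),
        effects=effects,
        cell_modifiers=cell_mod_df,
        z_unit_log2=z_unit,
        bead_sd=config.bead_sd,
        well_sd=config.well_sd,
        seed=int(seed),
        config=config,
    )
    return SimulatedScreen(beads=beads, samples=samples, panel=panel, truth=truth)


def simulate_reference_rnaseq(
    truth: ScreenTruth,
    n_cell_lines: int = 96,
    target_r: float = 0.9,
    n_decoy_genes: int = 1000,
    low_expression_fraction: float = 0.1,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Paired panel-measurement and RNA-seq reference matrices for recall.

    Returns ``(panel_matrix, rnaseq)``: the panel's ordinary probes measured
    across ``n_cell_lines`` reference cell lines, and a log2 RPKM-scale
    reference containing each matched gene (correlated with the panel
    measurement at ``target_r``) plus ``n_decoy_genes`` independent decoys.
    A fraction of matched genes is assigned a low reference mean to exercise
    the low-expression annotation.
    """
    if n_cell_lines < 3:
        raise ValueError("need at least 3 reference cell lines")
    if not -1.0 <= target_r <= 1.0:
        raise ValueError("target_r must be in [-1, 1]")
    rng = np.random.default_rng(seed)
    ordinary = [g for g, lv in truth.invariant_assignment.items() if lv == 0]
    cells = [f"REF{i + 1:02d}" for i in range(n_cell_lines)]

    x = rng.standard_normal((len(ordinary), n_cell_lines))
    panel_matrix = pd.DataFrame(
        truth.baselines[ordinary].to_numpy()[:, None] + x, index=ordinary, columns=cells
    )
    noise = rng.standard_normal((len(ordinary), n_cell_lines))
    y = target_r * x + math.sqrt(max(0.0, 1.0 - target_r**2)) * noise
    means = np.maximum(truth.baselines[ordinary].to_numpy() - 3.0, 0.5)
    low = rng.random(len(ordinary)) < low_expression_fraction
    means = np.where(low, 0.2, means)
    matched = pd.DataFrame(means[:, None] + y, index=ordinary, columns=cells)

    decoys = pd.DataFrame(
        rng.uniform(0.0, 9.0, size=n_decoy_genes)[:, None]
        + rng.standard_normal((n_decoy_genes, n_cell_lines)),
        index=[f"DECOY{i + 1:05d}" for i in range(n_decoy_genes)],
        columns=cells,
    )
    rnaseq = pd.concat([matched, decoys])
    return panel_matrix, rnaseq


def simulate_touchstone(
    truth: ScreenTruth | None = None,
    n_reference_perts: int = 50,
    include_kdoe: bool = True,
    n_cell_lines: int = 1,
    genes=None,
    planted_pert: str | None = None,
    planted_kd_id: str = "KD_SHARED",
    planted_strength_z: float = 4.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """A reference (touchstone) signature collection of z-score vectors.

    Signatures are standard-normal noise; when ``planted_pert`` names an
    active compound of ``truth`` and KD/OE classes are included, one
    knockdown signature shares that compound's affected module (same signed
    shifts), enabling planted-recovery checks of the similarity engine.

    Returns ``(signatures, meta)`` where signatures is genes x signature-ids
    and meta carries pert_id / pert_type / cell_id / pert_idose / pert_itime.
    """
    if n_reference_perts < 10:
        raise ValueError("need at least 10 reference perturbagens")
    rng = np.random.default_rng(seed)
    if genes is None:
        if truth is None:
            raise ValueError("pass either truth or an explicit gene index")
        genes = [g for g, lv in truth.invariant_assignment.items() if lv == 0]
    genes = pd.Index(genes)
    cells = [f"TCL{i + 1}" for i in range(n_cell_lines)]

    cols = {}
    meta_rows = []

    def add(pert_id: str, pert_type: str, cell: str, vec: np.ndarray) -> None:
        sid = f"{pert_id}:{cell}"
        cols[sid] = vec
        meta_rows.append(
            {
                "signature_id": sid,
                "pert_id": pert_id,
                "pert_type": pert_type,
                "cell_id": cell,
                "pert_dose": "10 uM" if pert_type == "CP" else "na",
                "pert_time": "24 h",
            }
        )

    type_cycle = ["CP", "CP", "KD", "OE"] if include_kdoe else ["CP"]
    for cell in cells:
        for i in range(n_reference_perts):
            ptype = type_cycle[i % len(type_cycle)]
            add(f"REF_{ptype}{i + 1:03d}", ptype, cell, rng.standard_normal(len(genes)))
        for i in range(max(2, n_reference_perts // 10)):
            add(f"REF_CTRL{i + 1:02d}", "CTRL", cell, rng.standard_normal(len(genes)))
        if planted_pert is not None:
            if truth is None or planted_pert not in truth.effects:
                raise ValueError(f"{planted_pert!r} is not an active compound of the truth")
            eff = truth.effects[planted_pert]
            base = rng.standard_normal(len(genes))
            idx = genes.get_indexer([g for g in eff["genes"] if g in genes])
            signs = np.array(
                [eff["signs"][g] for g in eff["genes"] if g in genes], dtype=float
            )
            planted_vec = base.copy()
            planted_vec[idx] += signs * planted_strength_z
            add(planted_pert, "CP", cell, planted_vec)
            if include_kdoe:
                kd = rng.standard_normal(len(genes))
                kd[idx] += signs * planted_strength_z
                add(planted_kd_id, "KD", cell, kd)

    signatures = pd.DataFrame(cols, index=genes)
    meta = pd.DataFrame(meta_rows).set_index("signature_id")
    return signatures, meta
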