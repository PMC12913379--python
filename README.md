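# neurocmap

Connectivity mapping for bead-based neuronal transcriptional screens.

Targeted bead-array assays in the L1000 family measure a few hundred
transcripts per well across thousands of perturbed wells — patient-derived
neurons exposed to libraries of neuroactive compounds at multiple doses and
time points. `neurocmap` implements the complete analysis stack for such
screens:

* **Five-level signature processing** — raw bead fluorescence (level 1) →
  per-gene median fluorescence intensity, MFI (level 2) → per-well
  calibration against a 10-level invariant-gene ladder followed by
  within-plate quantile normalization (level 3) → gene-wise robust z-scores
  against all samples on the detection plate (level 4) → weighted collapse
  of biological replicates into one signature per
  (perturbagen, cell line, dose, time) group (level 5).
* **QC / activity metrics** per replicate set, with panel size G:
  - replicate correlation `CC = Q75( Spearman(z_i, z_j) : i < j )`
  - signature strength `SS = #{ g : |mean(z_g) * sqrt(n)| > 2 }`
  - transcriptional activity score `TAS = sqrt( SS * max(CC, 0) / G )`
* **Connectivity queries** — an up/down gene-set query is scored against
  every signature with the weighted two-sided enrichment score (WTCS, a
  |z|-weighted Kolmogorov–Smirnov running sum), normalized within
  (cell line, perturbagen type) groups (NCS), and converted to **tau**, the
  signed percentile of |NCS| against a reference ("touchstone")
  distribution on [−100, +100]. Median tau across cell lines ranks
  compounds as *mimics* (tau > 0) or *reversers* (tau < 0) of the queried
  expression change.
* **Recall validation** — probe fidelity against an orthogonal RNA-seq
  reference (recall rank = % of reference genes correlating better than the
  matched gene; pass < 5%) and compound signature recall against an
  external signature collection (TAS ≥ 0.212 activity gate, rank
  threshold).
* **A ground-truth simulator** that emits bead-level screens, reference
  RNA-seq, and touchstone collections with planted compound effects, so the
  whole stack is testable end to end without any external data.

## Worked example

Simulate a small screen (3 cell lines × 12 compounds × 2 doses × 3
replicates, half the compounds active on 20-gene modules), process it, and
query it with one planted module:

```python
import neurocmap as nc

cfg = nc.ScreenConfig(n_cell_lines=3, n_compounds=12, n_genes=120,
                      invariant_per_level=4, vehicle_wells_per_plate=4)
screen = nc.simulate_screen(cfg, seed=11)
result = nc.process_screen(screen.beads, screen.samples, screen.panel)

m = result.metrics
print(m[["cc", "ss", "tas", "n_replicates", "pert_id", "pert_type"]].head(4).round(3))

active = screen.truth.active_compounds()
print("vehicle TAS (median): %.3f" % m[m.pert_type == "CTRL"].tas.median())
print("active TAS (median):  %.3f" % m[m.pert_id.isin(active)].tas.median())

cpd = active[0]
eff = screen.truth.effects[cpd]
query = nc.QuerySignature(
    up=tuple(g for g in eff["genes"] if eff["signs"][g] > 0),
    down=tuple(g for g in eff["genes"] if eff["signs"][g] < 0),
)
res = nc.run_query(query, result.level5)
print(nc.summarize_median_tau(res).summary.head(3).to_string(index=False))
```

Output:

```
                           cc  ss    tas  n_replicates pert_id pert_type
replicate_group
CPD001:CL1:0.5 uM:24 h  0.049   5  0.045             3  CPD001        CP
CPD001:CL1:5 uM:24 h    0.141   7  0.091             3  CPD001        CP
CPD002:CL1:0.5 uM:24 h  0.146   5  0.078             3  CPD002        CP
CPD002:CL1:5 uM:24 h   -0.020   3  0.000             3  CPD002        CP
vehicle TAS (median): 0.083
active TAS (median):  0.349
pert_id  n_cell_lines  median_tau classification
 CPD004             3   95.833333          mimic
 CPD005             3   66.666667          mimic
 CPD008             3   25.000000          mimic
```

The inactive compound CPD001/CPD002 groups sit at vehicle-level TAS, while
planted-active compounds score several-fold higher; querying the screen
with CPD004's own planted up/down module returns CPD004 as the top mimic at
median tau ≈ 96 across the three cell lines. Swapping the up and down lists
negates every score and returns the same compound as the top reverser.

The same workflow is available from the shell:

```bash
neurocmap simulate --seed 5 --out screen/
neurocmap process  --beads screen/beads.csv --panel screen/panel.tsv \
                   --samples screen/samples.tsv --out processed/
neurocmap query    --level5 processed/level5.gct --up up.grp --down down.grp \
                   --out query/
neurocmap embed    --level5 processed/level5.gct \
                   --metrics processed/signature_metrics.tsv --seed 9 \
                   --out coords.tsv
```

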