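# Methods

This note documents the models, numerical conventions and design choices
behind `neurocmap`, in the order data flows through the package.

## Five-level signature processing

**Level 1 → 2 (bead medians).** Raw fluorescence intensities are grouped by
(plate, well, bead barcode) and collapsed to the median, yielding one MFI
value per (gene, well). The panel couples exactly one gene to each barcode,
so no peak deconvolution is needed. Gene/well pairs with no beads become
missing values and stay missing through level 3; medians and correlations
exclude missing entries pairwise.

**Invariant-ladder calibration.** Each well is calibrated against 10
invariant expression-level sets ("ladder"). The per-level median of
log2(MFI + 1) defines calibration nodes mapped to the canonical ladder
values. The canonical ladder is configurable; the default is a geometric
ladder 2^k, k = 6..15 — only its strictly monotone shape matters, since
calibration is relative. The calibration curve is piecewise-linear through
the nodes with linear extrapolation beyond the end segments; non-monotone
observed node sequences are isotonic-adjusted first (with a warning), and
when at least 7 nodes are available a loess-style smooth (span 0.9) of the
targets replaces the raw nodes — 10 points under-determine a free loess
fit, so the smooth is a stabilizer, not an estimator. Calibration operates
on log2(FI + 1) and maps back to fluorescence scale. Wells with fewer than
2 usable ladder levels are flagged failed-QC, passed through bit-identical,
and excluded from all later levels; a per-well QC table records node
counts, post-calibration residuals and the isotonic flag.

Because the calibration curve has finitely many nodes, a smooth nonlinear
well distortion leaves residuals of order 1e-3 log2 units. These are
negligible against realistic noise, but they mean the idealized statement
"a distortion-only screen z-scores to exactly zero" holds only when
distortions are disabled; with the default noise levels the residuals are
two orders of magnitude below the noise floor.

**Quantile normalization** is scoped to the detection plate: after
normalization every well on a plate has the same empirical distribution,
the mean of the plate's sorted columns. Ties receive the mean of the target
quantiles they span (exact tie-group means, not midpoint interpolation).
With missing values, each column is mapped through the mean quantile
function on a common probability grid. Single-well plates are returned
unchanged with a warning.

**Robust z-scores** use the plate as reference distribution:
`z = (x − median) / (1.4826 · MAD)` with median/MAD across all samples of
the gene's plate, computed on log2(x + 1) of the level-3 values (the
`log2_before_zscore` flag controls the transform; the statistic itself is
scale-agnostic). The MAD is floored at 1e-6; rows constant across the plate
are defined as z = 0. Vehicle wells are included in the reference
distribution — the reference is "all samples on the plate", and with a
compound library in which any single perturbation affects a small gene
module, the plate median/MAD are dominated by nulls anyway. Plates need at
least 3 samples. Invariant-ladder probes are excluded from the z-score
space onward: calibration pins them to the ladder, so their post-
calibration variation is measurement error that the MAD floor would
amplify, and they carry no biological signal.

**Replicate collapse (MODZ-style).** Replicates of one
(perturbagen, cell line, dose, time) group are combined as a weighted
average with weight_i ∝ mean Spearman correlation of replicate i to the
others, floored at 0.01 and normalized to sum to one. One replicate passes
through; two replicates average equally (their mutual correlations are
symmetric). Spearman uses average-rank ties over all panel genes — the
panel is small, so no landmark subset is used. The output is a convex
combination of the replicate profiles whenever all weights are positive.

## QC metrics

* **CC** — the 75th percentile (linear interpolation between order
  statistics) of all pairwise Spearman correlations among a group's
  level-4 profiles. A single replicate has no pairs; its CC is 0.
* **SS** — `Za = mean(z) · sqrt(n)` per gene, and SS counts `|Za| > 2`
  with a strict inequality (|Za| exactly 2 is not counted). The moderation
  is the standard-error scaling of a replicate mean; the literal unscaled
  alternative `Za = mean(z) · n` is available as `za_mode="n_mean"`.
* **TAS** — `sqrt(SS · max(CC, 0) / G)` with G the panel size (467 by
  default). The square root places the 0.212 activity threshold
  meaningfully inside [0, 1]; the unrooted product is available as
  `tas_mode="linear"`. Negative CC is clamped: anti-correlated replicates
  carry no activity evidence, so TAS = 0.
* **F-tail helper** — `P(F_{d1,d2} > f)` through the regularized
  incomplete beta function, for one-way group comparisons in reports.

Whether SS should use collapsed level-5 values or the replicate mean is
indistinguishable in the underlying method description; the replicate mean
is used (identical when collapse weights are equal).

## Connectivity scoring

A query is a disjoint up/down pair of gene lists (size bounds 10–150 per
list by default, matching platform practice). Queries from
differential-expression tables take the top `n_up` genes by descending
log2 fold change among positives and the top `n_down` by ascending among
negatives (defaults 137/150), after an optional significance filter;
duplicate gene ids upstream are resolved by keeping the largest |log2FC|;
genes absent from the panel are dropped and counted — the method has no
way to score unmeasured genes, so log-and-drop is the explicit convention.

**WTCS.** Each list is scored against the signature ranked by descending z
(ties broken by gene id for determinism) with a weighted KS running sum:
hits advance by |z| / Σ|z| over hits (GSEA weight 1), misses retreat by
1/(N − n_hits); the enrichment score is the extremum of the running sum.
`WTCS = (ES_up − ES_down)/2` when the two scores disagree in sign, else 0.
A query with one usable side scores with that side alone; a query with no
genes in the signature space yields a flagged missing value.

**NCS** divides each WTCS by the mean |WTCS| of same-sign scores within
its (cell line, perturbagen type) group — the documented platform
convention for cross-cell, cross-class comparability. A sign group of one
self-normalizes to ±1.

**Tau** is `sign(NCS) · 100 · fraction of touchstone |NCS| strictly below
|NCS|`, computed against the same cell line's touchstone distribution.
Strictly-less counting makes tau = 0 for a zero score and keeps ties from
inflating percentiles. Vehicle-control signatures are excluded from the
touchstone by default (`touchstone_types=("CP", "KD", "OE")`): controls are
null by construction and would deflate the percentile scale.

**Median-tau summaries.** Within each cell line a perturbagen is
represented by its strongest signature (max |NCS| — in a two-dose screen
this is the responsive-dose exemplar); the summary statistic is the median
of these per-cell-line taus, with the even-count median the midpoint of the
central pair. Descending order gives mimics, ascending gives reversers;
top-k shortlists default to 25.

**Touchstone similarity** seeds a query from a selected signature's own
extreme genes (50/50 by default, capped at half the gene space) and scores
it against the whole collection including knockdown/overexpression
classes, so genetic perturbagens sharing a compound's mechanism surface.
A direct signature-to-signature Spearman ranking is available as
`method="correlation"`. Ties rank lexicographically by perturbagen id.

## Recall validation

**Probe recall** computes, per probe, the Spearman correlation across
shared cell lines to every gene of an RNA-seq reference; the recall rank is
the percentage of reference genes with *strictly* higher correlation than
the probe's own gene (ties do not penalize the match), and a probe passes
below 5%. Probes whose matched gene is absent from the reference or
constant in either matrix are excluded from the denominator and listed —
they have no defined rank. Failed probes whose reference mean (log2 RPKM
scale) falls below 1.0 are annotated low-expression: poor recall there
reflects absent signal, not a faulty probe. The 1.0 default operationalizes
a qualitative "low average expression" criterion and is configurable.

**Signature recall** gates test signatures on TAS ≥ 0.212, correlates each
active signature with every reference signature over the shared gene
space, ranks descending (rank 1 = best), and flags recall when the matched
compound's best rank is at or below the threshold (default 190, the ~10%
percentile of a 1,886-signature reference collection).

## The simulator

The generator emulates the screen the pipeline is built for: 467 ordinary
probes plus an 80-probe invariant ladder (10 levels × 8), one 384-well
detection plate per (cell line, replicate) carrying every compound × dose
well plus vehicle controls. Defaults: 6 cell lines × 60 compounds ×
2 doses × 3 replicates, 3 beads per gene per well, half the compounds
active on 20-gene modules (half the module up, half down) at 3–5 z, high
dose 1.5× the low-dose effect.

On the log2 fluorescence scale, a bead value is
`a_w (b_g + c_{g,cell} + e_{g,w} + ε_{g,w}) + d_w + η_bead`: gene baseline
(uniform on 4–12 log2 units; invariant probes sit exactly on the canonical
ladder), per-cell-line offsets (sd 0.3, zero for invariant probes), the
planted effect, well-level noise (sd 0.1), a monotone affine well
distortion (slope 0.85–1.15, offset ±0.5 — what the calibration must
undo), and bead noise (sd 0.2). Planted effects are specified in z-units
and converted to log2 shifts via the expected per-gene dispersion
`sqrt(well_sd² + median-of-beads sd²)` (floored at 0.1 so noise-free runs
still carry effects), so a planted "4 z" lands near z = 4 after
processing. Everything is a pure function of (config, seed).

What the simulator does *not* model: saturation and optical cross-talk of
real bead scanners, correlated gene-gene covariance beyond the planted
modules, batch effects between plates beyond the affine distortion, and
real biological pathway structure. Passing tests therefore demonstrate
that the statistics recover what they are defined to recover under
realistic noise — not that any particular biological claim holds on real
screens.

Companion generators produce (a) paired panel/RNA-seq matrices whose
matched genes correlate at a target r, with independent decoys and a
low-expression stratum, for probe-recall validation; and (b) touchstone
signature collections of standard-normal z-vectors with CP/CTRL/KD/OE
classes, optionally planting a knockdown that shares an active compound's
module for similarity-recovery checks.

## Null calibration and known limitations

Under the default noise model, null replicate groups (n = 3) have
SS ≈ 20 of 467 and CC near zero, putting TAS around 0.03–0.07; the maximum
over all ~700 groups of a no-effect screen sits near 0.1, the conventional
inactivity band — occasional seeds push single groups marginally above it,
which is the expected behaviour of an extreme-order statistic rather than
a miscalibration. Random queries against a null touchstone give median
taus centered at zero.

Other limitations: the GCT support is the text 1.3 dialect only (no
GCTX/HDF5); identifier mapping is strictly offline via caller-supplied
two-column tables; quantile normalization with missing values uses a grid
approximation rather than exact tie-group means; and the t-SNE embedding
is deterministic only for a fixed seed and scikit-learn version.

## Problem sizes used in tests

The unit suite runs a compact planted screen (3 cell lines × 12 compounds,
120 genes); the end-to-end acceptance checks run the reference-scale
screen (6 × 60 × 2 × 3, 467 genes, ~3.8M bead rows, about 30 s to simulate
and process), a no-effect screen at the same scale, 200 random-query null
draws, and 500-probe recall experiments — sizes chosen so the full suite
exercises the defaults of the generator while remaining comfortable on a
single CPU.
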