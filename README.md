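# scregnet

Reusable, tested implementations of the bespoke computational procedures
behind a paired scRNA-seq / scATAC-seq developmental atlas of mouse
pharyngeal endoderm (E9.5–E12.5) and its Foxn1-knockout comparison: the
tissue that gives rise to thymus, parathyroid and ultimobranchial body.
The package is aimed at computational biologists who want the statistical
machinery of such an atlas — auditable QC accounting, batch-aware
reduction, chromatin feature scoring, co-accessibility-based GRN inference
with in-silico knockouts, and knockout-versus-atlas staging — as plain
library functions, exercised end to end on a seeded synthetic-data
generator rather than on the multi-gigabyte originals.

## What is implemented

**QC ledger** (`scregnet.qc`, `scregnet.study`). Ordered cell- and
cluster-level exclusion rules ("over 7% mitochondrial UMIs" is strict,
"at least 80%" is inclusive) produce a telescoping ledger,
remaining_i = remaining_{i−1} − removed_i, with each removed cell
attributed to the first rule it fails. The per-sample doublet quota is
⌊n²/divisor⌋ with divisor 100,000 (the value consistent with the study's
printed removals, e.g. 186 of 4320 cells). Replaying the study's printed
tables reproduces every total: 57,850 → 54,044 (atlas), 29,276 → 21,904
(knockout), 13,953 → 13,396 (scATAC doublets), 10,890 final scATAC cells.

**Batch-aware reduction** (`scregnet.reduce`). The covariate design holds
total UMI (1 column), cell-cycle indicators (3), and replicate contrasts
within timepoint (Σ_t (r_t − 1) columns; the atlas structure 2,3,3,2 gives
6, hence d = 10). Variable genes are chosen by the dispersion of
*residuals* after least-squares regression on this design, z-scored in
equal-count mean bins; scaling subtracts fitted values and divides by the
residual sd. PCA retains components whose covariance eigenvalues exceed
the Marchenko–Pastur upper edge σ²(1 + √(p/n))²; query cells are centered
with atlas gene means and multiplied by the loading matrix, so atlas cells
project onto their own training scores.

**Chromatin features** (`scregnet.atac`). Strand-aware promoter windows
[TSS−2000, TSS+100]; greedy iterative-overlap merging of fixed-width 501 bp
peaks by descending significance; the cluster-specificity index
τ = Σ_i (1 − x_i)/(N − 1) on max-normalized log₂ cluster means; mean
per-base conservation filtering; chromVAR-style motif deviations —
(observed − expected)/expected accessibility in motif-bearing peaks,
z-scored against 50 GC- and accessibility-matched background peak sets —
and motif–gene pairing within TF families (correlation > 0.35, per-cluster
motif score in the top decile).

**GRN inference** (`scregnet.grn`). Low-overlapping kNN cell aggregates
(k = 100, pairwise overlap ≤ 0.8); aggregate-level Pearson co-accessibility
of peak pairs within 250 kb (FDR < 10⁻¹⁰, r ≥ 0.5, variability filter);
base GRN linking a peak to a gene by TSS overlap or co-accessibility ≥ 0.5
with a TSS peak, candidate regulators read off motif hits; per-cluster
bagging ridge regression (α = 10, 20 bags) with pruning (edge p ≤ 0.001,
|w| > 0.005, regulator in the cluster's marker set) and refit; betweenness
centrality, outdegree, expression specificity, and regulator ranking by
focus-set intersection with Leiden communities of the top-200 subgraph.

**Perturbation and staging** (`scregnet.perturb`). In-silico knockout:
δ⁰ = −baseline on the KO genes, then δ ← Wᵀδ with the KO genes clamped,
for depth 5 — the truncated geometric series of the reduced system, which
converges to the (I − Wᵀ_ff)⁻¹ fixed point. Projection of perturbed cells
by 50-nearest-neighbor plurality vote with vote-fraction probabilities;
quasi-Poisson GLM confidence intervals for cluster abundances (offset
log replicate totals, Pearson-X² dispersion); the lineage probability
filter (score ≥ 0.8 and sentinel gene detected); equal-count pseudotime
binning; a dynamic-gene screen (max log₂ fold change across 20 periods
> 0.75, Kruskal–Wallis q < 0.01); and staging by Pearson correlation of
rank-transformed pseudobulks against atlas bins.

**Synthetic data** (`scregnet.simulate`). Seeded generators for clustered
scRNA counts (replicate batch effects, cell-cycle offsets, mitochondrial
fractions, exact planted QC violations, contaminant clusters), capped
scATAC insertion counts over promoter/distal peak geometry with motif
hits, and linear structural ground-truth GRNs with fixed-point expression,
including a clamped-knockout variant and a 1-D pseudotime trajectory.

## Worked example

`analysis/` contains the numbered pipeline drivers. After
`python analysis/01_simulate_data.py`, running
`python analysis/02_qc_ledgers.py` prints:

```
atlas: 57850 -> 54044 cells
knockout: 29276 -> 21904 cells
atac_doublets: 13953 -> 13396 cells
scATAC per-sample final counts sum to 10890
synthetic atlas ledger:
               rule  cells_removed  cells_remaining
     mito_over_7pct             90             2810
    mito_under_1pct             20             2790
hbb_log_norm_over_1              5             2785
     under_2000_umi             30             2755
```

The first block replays the study's printed exclusions exactly; the second
runs the same rules on the synthetic atlas, where the generator planted
exactly 90/20/5/30 violations — the ledger recovers each count and
telescopes to the final total. Downstream drivers report, among others,
`tau: planted-specific median 0.743 vs background median 0.053`
(cluster-specific peaks score far above background), `edge recovery at
default pruning: precision 1.000, recall 1.000` on the ground-truth GRN at
n = 2000 cells, and `simulated vs experimental KO of g000: Spearman
rho = 0.712` between depth-5 propagated shifts and fold changes measured
on cells simulated with the gene truly clamped off.

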