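# Methods

This note documents the models and procedures implemented in `scregnet`,
the parameters that matter, what the synthetic-data generator does and
does not emulate, and the numerical and design choices made where the
published description of such pipelines leaves the details open.

## QC ledger

Filtering is modeled as an ordered list of rules over cell metadata.
Verbal thresholds are mapped to strict or inclusive comparisons by their
wording: "over"/"under" are strict, "at least"/"at most" inclusive. A cell
failing several rules is removed once and attributed to the *first* rule
it fails in the declared order; this makes removal counts additive and the
ledger telescoping (remaining_i = remaining_{i−1} − removed_i), which is
what allows published per-rule counts to be replayed and audited. The
final count is order-invariant; only the attribution depends on order.

The hemoglobin rule operates on log-normalized expression: counts rescaled
to 10,000 per cell, log(1 + x), base 2 in the atlas preset and natural log
in the knockout preset (both presets appear in the original workflows; the
base is a parameter).

The scATAC doublet quota removes ⌊n²/divisor⌋ cells per sample. The
divisor defaults to 100,000: the published removals for each sample
(186/4320, 16/1273, 127/3576, 228/4784) are consistent with 100,000 and
not with the nominal 10,000 in the printed formula, so the divisor is
exposed as a parameter and the consistent value is the default.

`scregnet.study` carries the study's printed accounting tables (starting
counts, per-rule removals, per-sample breakdowns) as package data; the
replay functions recompute every downstream total from them rather than
storing the totals.

## Covariate design and reduction

The batch-correction design has d = 1 + 3 + Σ_t (r_t − 1) columns: raw
total UMI, all three cell-cycle indicators, and replicate contrasts within
each timepoint encoded as +1/−1 adjacent-replicate columns (redundant
columns omitted by construction). All three phase indicators are kept even
though they are collinear with the intercept; every regression in the
package goes through `numpy.linalg.lstsq` (minimum-norm pseudoinverse
solution), so rank deficiency changes nothing about fitted values or
residuals — it only triggers a warning.

Gene selection uses the dispersion of residuals: per gene, fit the design
by least squares on depth-normalized (not logged) counts and compute
log(residual variance / mean), then z-score within 20 equal-count mean
bins and keep genes with mean > 0.1 and scaled dispersion > 0.8 (all three
are parameters; the cutoffs are the legacy variable-gene defaults).
Residual variances within 1e−12 of rounding noise (relative to the gene's
total variance) are treated as exactly zero, and such genes are never
selected. Scaling subtracts the fitted values and divides by the residual
sd (ddof 1); genes fit exactly by the design map to all-zeros rather than
amplified rounding error.

PCA retention uses the Marchenko–Pastur upper edge σ²(1 + √(p/n))² with
σ² = 1 for unit-scaled genes, p = genes, n = cells; eigenvalues are those
of the sample covariance (s²/(n−1) from the SVD of the centered matrix).
A caveat documented deliberately: at finite size the largest pure-noise
eigenvalue fluctuates around the asymptotic edge (Tracy–Widom) and
exceeds it in a non-negligible fraction of draws — about 7% at
n = 2000, p = 200 — so "retain nothing on pure noise" holds usually but
not almost surely at that size. The retention rule is kept as the plain
asymptotic edge; no finite-sample inflation factor is applied.

Projection centers queries with the *atlas* gene means and applies the
atlas loadings, so atlas cells reproduce their training scores; genes
missing from a query contribute zero after centering (counted, warned,
and an error above a configurable fraction). Scaled and unscaled
projection modes correspond to the atlas and knockout presets.

## Chromatin features

Coordinates are BED-style 0-based half-open throughout. The promoter
window is [TSS−2000, TSS+100] in inclusive genome coordinates, mirrored on
the minus strand, then converted to half-open; annotation precedence is
promoter > exonic > intronic > distal and is independent of peak order.
Iterative-overlap merging is greedy on descending significance; an
optional filter requires retained peaks to be supported by at least two
pseudobulk replicates.

τ = Σ(1 − x_i)/(N − 1) is computed on cluster-mean accessibility that is
rescaled to 10,000 per cluster profile, log₂(x+1)-transformed, and
per-peak max-normalized; all-zero peaks are reported as missing, and
N < 2 is an error.

Motif deviations follow the chromVAR scheme. Expected accessibility
assumes cell-independent peak usage, E[cell, motif] =
cell_total · (motif peak totals / grand total), computed on raw insertion
counts (normalization mode flagged as an open choice in the original
description). Backgrounds are 50 peak sets matched in a 10×10 grid of GC
and mean-accessibility deciles, sampled with replacement when a bin is
thin; the z-score subtracts the background mean and divides by the
background sd, computed in two passes so that degenerate backgrounds give
an exactly zero spread (reported as undefined) instead of rounding dust.
Per-cluster motif scores subtract the minimum cluster average, so they are
non-negative with at least one exact zero; pairs are the top motif score
per gene plus the top correlated gene per motif within each family,
retained at correlation > 0.35 and a motif score at or above the cluster's
90th percentile (boundary ties included).

## GRN inference

Aggregates are seeded at random cells, extended to the k = 100 nearest
neighbors in the reduced space, and accepted if the overlap fraction with
every accepted aggregate is ≤ 0.8; up to 500 seeds are tried. Aggregate
accessibility is summed, rescaled to 10,000 and log₂-transformed. Peak
pairs within 250 kb (midpoint to midpoint — the anchor is unspecified in
the original, midpoint is symmetric) on one chromosome are Pearson-
correlated; p-values come from the t statistic with df = aggregates − 2,
BH-adjusted; retention requires FDR < 10⁻¹⁰, correlation ≥ 0.5, and both
peaks above the 0.35 variance quantile across aggregates (the variability
unit is ambiguous in the original; the quantile reading is the default and
a value ≤ 0 disables the filter).

The base GRN links a peak to a gene if it overlaps the TSS (strength 1) or
has co-accessibility ≥ 0.5 with a TSS peak of the gene; candidate
regulators are TFs whose motifs hit any linked peak; self-edges are
dropped. Cluster refinement ridge-regresses each target on its candidates
(centered within cluster, α = 10, no intercept) over 20 bootstrap bags of
size n. The edge weight is the mean bagged coefficient. The edge p-value
is 2·t_sf(|mean| / sd_bags, df = bags − 1): the across-bag standard
deviation is used as the bootstrap standard error of the coefficient.
(Dividing it by √bags, as a literal one-sample t-test would, treats
bootstrap replicates as independent observations and drives null p-values
toward zero; with the bootstrap-SE form, null p-values are near-uniform
and a noise target prunes completely, which is the behavior the pruning
thresholds presuppose.) Pruning keeps edges with p ≤ 0.001, |w| > 0.005
and, when marker sets are supplied, regulator ∈ cluster markers; surviving
regulator sets are refit. Betweenness centrality is the unnormalized
directed shortest-path count (networkx); specificity is cluster mean
expression over the median of cluster means; regulator ranking sorts by
|targets ∩ focus| with lexicographic tie-breaks, and the top-200 subgraph
is partitioned by Leiden at resolution 2 (pluggable partitioner).

## Knockout, projection, abundance, staging

The knockout iterates δ ← Wᵀδ with the KO genes clamped at −baseline for
5 steps. On the free (non-KO) genes this equals the truncated geometric
series Σ_{t<depth} (Wᵀ_ff)^t Wᵀ_fk(−baseline_k) and converges to the
(I − Wᵀ_ff)⁻¹ fixed point when the free block is stable; the clamped
final-state form is used (rather than an unclamped power sum) because it
is the only reading under which the chain example and the fixed-point
limit are simultaneously exact. Clipping modes: none, non-negative
(default), or observed range.

Classification is 50-NN plurality voting in the shared principal
subspace, probabilities are vote fractions, ties go to the
lexicographically smallest cluster id (determinism over unspecified
behavior), and embedding positions average the neighbors'. Abundance
responses are per-replicate sums of assignment probabilities multiplied by
k and rounded; the GLM is Poisson log-link with genotype (and optional
batch) covariates and offset log(replicate cell totals), with dispersion
φ = Pearson X²/df rescaling the standard errors and 1.96·SE Wald
intervals on the natural-log scale (the log base of reported fold changes
is a parameter). Clusters under 100 weighted cells are flagged; a
genotype with zero cells yields a flagged NaN row, never an infinite
estimate. Forcing φ = 1 reduces exactly to the plain Poisson fit.

Pseudotime bins are contiguous equal-count groups (sizes differ by at
most one, larger bins first; ties broken by stable order). The
dynamic-gene screen splits cells into 20 equal-count periods and keeps
genes with log₂(max period mean + 1) − log₂(min period mean + 1) > 0.75
and a BH-adjusted Kruskal–Wallis q < 0.01 (the original screen's internal
test is unpublished; the rank-based one-way test is the pluggable
default, and the ε = 1 pseudocount guards zero period means). Staging
rank-transforms each raw-count pseudobulk over the dynamic set and
reports the two atlas bins with the largest Pearson correlations per
genotype.

## Synthetic data: what it emulates, and what it does not

The scRNA generator draws Poisson counts with per-cell lognormal size
factors (log-sd 0.3), per-replicate lognormal gene multipliers (log-sd
0.1) as batch effects, three-phase cell-cycle offsets (log-sd 0.15),
Beta-distributed mitochondrial fractions, and marker-boosted cluster
means; planted QC violations are realized exactly (background cells are
kept out of the violating range by construction) so ledger arithmetic is
testable to the cell. The scATAC generator places fixed-width 501 bp
peaks inside promoter windows or away from them, draws capped-at-4
Poisson insertion counts with 8-fold cluster-specific enrichment, and
Bernoulli motif hits at density 0.05. The truth GRN has root regulators
(hence trivially stable weights), uniform ±[0.3, 0.6] edge weights,
baselines in [2, 6], per-cell root jitter (sd 1.0) propagated to the
structural fixed point, and observation noise (sd 0.5).

Deliberately not emulated: UMI overdispersion beyond Poisson (a
negative-binomial flag would be the natural extension), ambient RNA,
doublet expression profiles, fragment-level ATAC structure, chromatin
co-accessibility decay with distance, TF→TF regulation in the default
truth network, and dropout beyond what Poisson sampling induces. Passing
tests therefore demonstrate correctness of the procedures under their own
statistical assumptions, not robustness to every artifact of real data.

## Problem sizes and calibration checks

The test and acceptance workloads are sized for a single CPU: 2000 cells
for GRN edge recovery, 100 pure-noise matrices of 2000×200 for the
Marchenko–Pastur retention rate, 500–2000 null simulations for
quasi-Poisson CI coverage, ~1000 network genes for the knockout
comparison, and exhaustive small instances (up to 6 peaks × 4 cells × 2
motifs) for the motif-deviation oracle.

The CI coverage check runs with 2 genotypes × 10 replicates and mean
cluster counts of 200 against Poisson truth. The asymptotic Wald interval
needs that much replication: at the 2 + 2 replicate design of the actual
knockout experiment the Pearson dispersion is estimated on 2 degrees of
freedom and the 1.96·SE interval undercovers substantially (~80% in
simulation). This is a known limitation of asymptotic quasi-likelihood
intervals at minimal replication, inherited from the original design, and
is why the calibration check is run in the regime the interval is meant
for.

## Known limitations

- The co-accessibility p-values assume independent aggregates; aggregates
  share cells (overlap up to 0.8), so the effective sample size is
  overstated and the FDR threshold should be read as a ranking device,
  as in the original pipeline.
- Betweenness, ranking and community steps operate on the pruned edge
  list; no attempt is made to reproduce any specific external tool's
  numerical output.
- The simplified distance-weighted gene activity score is an
  approximation and excluded from any accuracy claims.
- The Marchenko–Pastur retention caveat above: at moderate matrix sizes,
  pure noise occasionally clears the asymptotic edge.
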