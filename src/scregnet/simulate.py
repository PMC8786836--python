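"""Seeded synthetic scRNA, scATAC and ground-truth GRN generators.

The generators emulate the statistical structure of a multi-timepoint
single-cell developmental atlas: clustered UMI counts with replicate batch
effects, cell-cycle covariates and mitochondrial fractions; clustered
insertion counts over fixed-width chromatin peaks with promoter/distal
geometry and motif hits; and a linear structural gene-regulatory network
whose fixed-point expression supports edge-recovery and knockout tests.

All randomness flows through ``numpy.random.default_rng(seed)``; identical
specs with identical seeds produce bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse

HEMOGLOBIN_GENE = "Hbb-bt"

# QC-rule keys understood by planted_filter_counts, with the predicate each
# planted cell is guaranteed to violate (and background cells guaranteed not
# to, for keys that are present).
PLANTABLE_RULES = ("high_mito", "low_mito", "high_hemoglobin", "low_umi")


@dataclass
class ScRnaSimSpec:
    """Parameters of the clustered scRNA-seq UMI count generator.

    ``timepoints`` lists (label, n_replicates); cells are spread uniformly
    over replicates within timepoints.  ``cluster_means`` is an optional
    (n_clusters, n_genes) matrix of expected expression per unit size
    factor; when omitted, lognormal gene means with ``marker_fold``-boosted
    cluster markers are drawn.  Batch effects are per-replicate per-gene
    lognormal multipliers with log-sd ``batch_effect_sd``; depth is a
    per-cell lognormal size factor; mitochondrial fractions follow a Beta
    law.  ``planted_filter_counts`` plants exact numbers of cells violating
    the named QC rules (see ``PLANTABLE_RULES``).
    """

    n_cells: int = 2000
    n_genes: int = 200
    n_clusters: int = 4
    timepoints: tuple[tuple[str, int], ...] = (
        ("E9.5", 2),
        ("E10.5", 3),
        ("E11.5", 3),
        ("E12.5", 2),
    )
    cluster_means: np.ndarray | None = None
    mean_expression: float = 0.6
    marker_genes_per_cluster: int = 10
    marker_fold: float = 8.0
    cluster_separation_sd: float = 0.0  # extra additive marker shift, in units of Poisson sd
    batch_effect_sd: float = 0.1
    depth_log_mean: float = np.log(1.0)
    depth_log_sd: float = 0.3
    mito_beta: tuple[float, float] = (6.0, 150.0)
    cell_cycle_probs: tuple[float, float, float] = (0.6, 0.2, 0.2)
    cell_cycle_effect_sd: float = 0.15
    hemoglobin_rate: float = 0.05
    planted_contaminants: tuple[tuple[int, int], ...] = ()
    planted_filter_counts: dict[str, int] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if any(r < 1 for _, r in self.timepoints):
            raise ValueError("every timepoint needs at least one replicate")
        planted = sum((self.planted_filter_counts or {}).values())
        planted += sum(size for size, _ in self.planted_contaminants)
        if planted > self.n_cells:
            raise ValueError(
                f"planted cells ({planted}) exceed n_cells ({self.n_cells})"
            )
        unknown = set(self.planted_filter_counts or {}) - set(PLANTABLE_RULES)
        if unknown:
            raise ValueError(f"unknown planted filter keys: {sorted(unknown)}")


def _default_cluster_means(spec: ScRnaSimSpec, rng: np.random.Generator) -> np.ndarray:
    base = rng.lognormal(mean=0.0, sigma=0.8, size=spec.n_genes)
    base *= spec.mean_expression / base.mean()
    means = np.tile(base, (spec.n_clusters, 1))
    m = spec.marker_genes_per_cluster
    for k in range(spec.n_clusters):
        lo = (k * m) % spec.n_genes
        idx = (np.arange(m) + lo) % spec.n_genes
        means[k, idx] *= spec.marker_fold
        if spec.cluster_separation_sd > 0:
            # additive shift measured in Poisson standard deviations
            means[k, idx] += spec.cluster_separation_sd * np.sqrt(means[k, idx])
    return means


def simulate_scrna(spec: ScRnaSimSpec) -> ad.AnnData:
    """Draw a clustered scRNA-seq UMI count matrix with cell metadata.

    Returns an :class:`anndata.AnnData` with sparse integer ``X`` and obs
    columns ``timepoint``, ``replicate``, ``sample``, ``true_cluster``,
    ``mito_fraction``, ``cell_cycle_phase``, ``total_umi`` and
    ``is_contaminant``.  When ``planted_filter_counts`` is given, each
    listed rule is violated by exactly the requested number of cells.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_cells

    samples = [
        (tp, rep)
        for tp, n_rep in spec.timepoints
        for rep in range(1, n_rep + 1)
    ]
    sample_idx = rng.integers(0, len(samples), size=n)
    timepoint = np.array([samples[i][0] for i in sample_idx])
    replicate = np.array([samples[i][1] for i in sample_idx])
    sample = np.array([f"{samples[i][0]}_rep{samples[i][1]}" for i in sample_idx])

    n_contam = sum(size for size, _ in spec.planted_contaminants)
    cluster = rng.integers(0, spec.n_clusters, size=n).astype(object)
    contam_mask = np.zeros(n, dtype=bool)
    pos = n - n_contam
    for ci, (size, _marker_seed) in enumerate(spec.planted_contaminants):
        sl = slice(pos, pos + size)
        cluster[sl] = f"contaminant_{ci}"
        contam_mask[sl] = True
        pos += size

    means = spec.cluster_means
    if means is None:
        means = _default_cluster_means(spec, rng)
    means = np.asarray(means, dtype=float)
    if means.shape != (spec.n_clusters, spec.n_genes):
        raise ValueError("cluster_means must be (n_clusters, n_genes)")

    gene_names = [f"gene_{g:04d}" for g in range(spec.n_genes)] + [HEMOGLOBIN_GENE]
    n_genes = spec.n_genes + 1

    phase = rng.choice(["G1", "S", "G2M"], size=n, p=spec.cell_cycle_probs)
    phase_mult = {
        p: rng.lognormal(0.0, spec.cell_cycle_effect_sd, size=spec.n_genes)
        for p in ("G1", "S", "G2M")
    }
    batch_mult = {
        s: rng.lognormal(0.0, spec.batch_effect_sd, size=spec.n_genes)
        for s in {f"{tp}_rep{r}" for tp, r in samples}
    }
    depth = rng.lognormal(spec.depth_log_mean, spec.depth_log_sd, size=n)

    planted = spec.planted_filter_counts or {}
    plant_idx: dict[str, np.ndarray] = {}
    if planted:
        # planting uses the tail cells not used by contaminants, disjointly
        avail = np.flatnonzero(~contam_mask)
        rng.shuffle(avail)
        pos = 0
        for key in PLANTABLE_RULES:
            k = planted.get(key, 0)
            plant_idx[key] = avail[pos : pos + k]
            pos += k
            if len(plant_idx[key]) < k:
                raise ValueError("not enough cells to plant filter violations")

    if "low_umi" in planted:
        depth[plant_idx["low_umi"]] = 1e-6  # topped up to an exact total below

    rows = np.zeros((n, n_genes))
    for i in range(n):
        c = cluster[i]
        if isinstance(c, str):  # contaminant: its own marker signature
            ci = int(c.split("_")[1])
            crng = np.random.default_rng(
                spec.seed + 7919 * (ci + 1) + 104729
            )
            mu = means.mean(axis=0) * crng.lognormal(0.0, 1.0, size=spec.n_genes)
        else:
            mu = means[c]
        rate = mu * batch_mult[sample[i]] * phase_mult[phase[i]] * depth[i]
        rows[i, : spec.n_genes] = rate
    rows[:, spec.n_genes] = spec.hemoglobin_rate * depth
    X = rng.poisson(rows).astype(np.int64)

    hb = spec.n_genes
    if "high_hemoglobin" in planted:
        X[:, hb] = 0  # background guaranteed below the rule threshold
    totals = X.sum(axis=1)
    if "high_hemoglobin" in planted:
        idx = plant_idx["high_hemoglobin"]
        # log2(1 + 1e4 * c / total) > 1 requires c > total / 1e4
        X[idx, hb] = np.maximum(2 * totals[idx] // 10_000 + 2, 2)
        totals = X.sum(axis=1)
    if "low_umi" in planted:
        background = np.ones(n, dtype=bool)
        background[plant_idx["low_umi"]] = False
        short = background & (totals < 2000)
        for i in np.flatnonzero(short):  # rare with default depth
            X[i, 0] += 2000 - totals[i]
        idx = plant_idx["low_umi"]
        X[idx, 0] = np.maximum(1000 - X[idx].sum(axis=1) + X[idx, 0], 0)
        totals = X.sum(axis=1)

    mito = rng.beta(*spec.mito_beta, size=n)
    if {"high_mito", "low_mito"} & set(planted):
        mito = 0.0105 + (0.0695 - 0.0105) * rng.random(size=n)
        mito[plant_idx.get("high_mito", [])] = 0.075 + 0.05 * rng.random(
            len(plant_idx.get("high_mito", []))
        )
        mito[plant_idx.get("low_mito", [])] = 0.009 * rng.random(
            len(plant_idx.get("low_mito", []))
        )

    obs = pd.DataFrame(
        {
            "timepoint": pd.Categorical(timepoint),
            "replicate": replicate,
            "sample": sample,
            "true_cluster": [str(c) for c in cluster],
            "mito_fraction": mito,
            "cell_cycle_phase": pd.Categorical(phase, categories=["G1", "S", "G2M"]),
            "total_umi": totals,
            "is_contaminant": contam_mask,
        },
        index=[f"cell_{i:05d}" for i in range(n)],
    )
    adata = ad.AnnData(
        X=sparse.csr_matrix(X),
        obs=obs,
        var=pd.DataFrame(index=gene_names),
    )
    adata.uns["cluster_means"] = means
    return adata


@dataclass
class ScAtacSimSpec:
    """Parameters of the clustered scATAC insertion-count generator.

    Peaks are fixed-width 501 bp intervals.  A ``fraction_promoter_peaks``
    share is placed inside the strand-aware promoter window
    [TSS-2000, TSS+100] of a random TSS; the rest are distal.  A
    ``cluster_specific_fraction`` share of peaks is accessible mostly in one
    cluster.  Insertion counts are Poisson capped at ``max_insertions``.
    """

    n_cells: int = 500
    n_peaks: int = 300
    n_clusters: int = 4
    genome: tuple[tuple[str, int], ...] = (("chr1", 5_000_000), ("chr2", 5_000_000))
    n_genes: int = 40
    tss_table: pd.DataFrame | None = None
    fraction_promoter_peaks: float = 0.3
    cluster_specific_fraction: float = 0.3
    specific_fold: float = 8.0
    n_motifs: int = 20
    motif_hit_density: float = 0.05
    max_insertions: int = 4
    peak_width: int = 501
    base_rate: float = 0.5
    depth_log_sd: float = 0.25
    promoter_upstream: int = 2000
    promoter_downstream: int = 100
    seed: int = 0


def _random_tss_table(spec: ScAtacSimSpec, rng: np.random.Generator) -> pd.DataFrame:
    chroms, lengths = zip(*spec.genome)
    ci = rng.integers(0, len(chroms), size=spec.n_genes)
    margin = spec.promoter_upstream + spec.peak_width + 10
    tss = np.array(
        [rng.integers(margin, lengths[c] - margin) for c in ci]
    )
    return pd.DataFrame(
        {
            "gene": [f"tf_gene_{g:03d}" for g in range(spec.n_genes)],
            "chrom": [chroms[c] for c in ci],
            "tss": tss,
            "strand": rng.choice(["+", "-"], size=spec.n_genes),
        }
    )


def simulate_scatac(
    spec: ScAtacSimSpec,
) -> tuple[ad.AnnData, pd.DataFrame, pd.DataFrame]:
    """Draw (cells x peaks counts, peak BED table, peak x motif hit matrix).

    The BED table has 0-based half-open ``chrom, start, end, name`` plus a
    ``gc`` column used by motif-deviation background matching.  Counts never
    exceed ``max_insertions``.
    """
    rng = np.random.default_rng(spec.seed)
    genome = dict(spec.genome)
    total_len = sum(genome.values())
    if total_len < 3 * spec.n_peaks * spec.peak_width:
        raise ValueError("genome too small for the requested peak count")

    tss = spec.tss_table
    if tss is None:
        tss = _random_tss_table(spec, rng)

    n_prom = int(round(spec.fraction_promoter_peaks * spec.n_peaks))
    chroms = list(genome)
    # strand-aware promoter windows, for keeping distal peaks out of them
    windows: dict[str, list[tuple[int, int]]] = {}
    for row in tss.itertuples(index=False):
        if row.strand == "+":
            lo, hi = row.tss - spec.promoter_upstream, row.tss + spec.promoter_downstream
        else:
            lo, hi = row.tss - spec.promoter_downstream, row.tss + spec.promoter_upstream
        windows.setdefault(row.chrom, []).append((lo - spec.peak_width, hi + spec.peak_width))
    records = []
    for p in range(spec.n_peaks):
        if p < n_prom:
            row = tss.iloc[rng.integers(0, len(tss))]
            if row["strand"] == "+":
                lo, hi = row["tss"] - spec.promoter_upstream, row["tss"] + spec.promoter_downstream
            else:
                lo, hi = row["tss"] - spec.promoter_downstream, row["tss"] + spec.promoter_upstream
            center = int(rng.integers(lo, hi + 1))
            chrom = row["chrom"]
        else:
            for _ in range(1000):  # rejection sampling away from promoters
                chrom = chroms[rng.integers(0, len(chroms))]
                center = int(
                    rng.integers(spec.peak_width, genome[chrom] - spec.peak_width)
                )
                if not any(lo <= center <= hi for lo, hi in windows.get(chrom, [])):
                    break
            else:
                raise ValueError("genome too small to place distal peaks")
        start = max(0, center - spec.peak_width // 2)
        end = start + spec.peak_width
        if end > genome[chrom]:
            end = genome[chrom]
            start = end - spec.peak_width
        records.append((chrom, start, end, f"peak_{p:05d}"))
    peaks = pd.DataFrame(records, columns=["chrom", "start", "end", "name"])
    peaks["gc"] = rng.uniform(0.3, 0.7, size=spec.n_peaks)
    peaks["is_promoter_planted"] = np.arange(spec.n_peaks) < n_prom

    n_spec = int(round(spec.cluster_specific_fraction * spec.n_peaks))
    spec_peaks = rng.choice(spec.n_peaks, size=n_spec, replace=False)
    owner = rng.integers(0, spec.n_clusters, size=n_spec)
    peaks["specific_cluster"] = -1
    peaks.loc[peaks.index[spec_peaks], "specific_cluster"] = owner

    base = spec.base_rate * rng.lognormal(0.0, 0.5, size=spec.n_peaks)
    rates = np.tile(base, (spec.n_clusters, 1))
    for j, pk in enumerate(spec_peaks):
        rates[:, pk] = base[pk] / spec.specific_fold
        rates[owner[j], pk] = base[pk] * spec.specific_fold

    cluster = rng.integers(0, spec.n_clusters, size=spec.n_cells)
    depth = rng.lognormal(0.0, spec.depth_log_sd, size=spec.n_cells)
    lam = rates[cluster] * depth[:, None]
    X = np.minimum(rng.poisson(lam), spec.max_insertions).astype(np.int64)

    obs = pd.DataFrame(
        {
            "true_cluster": cluster.astype(str),
            "depth_factor": depth,
        },
        index=[f"atac_cell_{i:05d}" for i in range(spec.n_cells)],
    )
    adata = ad.AnnData(
        X=sparse.csr_matrix(X),
        obs=obs,
        var=peaks.set_index("name"),
    )

    hits = (
        rng.random((spec.n_peaks, spec.n_motifs)) < spec.motif_hit_density
    )
    motif_hits = pd.DataFrame(
        hits,
        index=peaks["name"],
        columns=[f"motif_{m:03d}" for m in range(spec.n_motifs)],
    )
    return adata, peaks, motif_hits


@dataclass
class GroundTruthGrn:
    """A linear structural gene-regulatory network used as simulation truth.

    ``edges`` holds (regulator, target, weight) rows over ``genes``;
    expression deviations from ``baseline`` satisfy d = W'd + noise, so the
    weight matrix must have spectral radius < 1 when ``stable`` is set.
    """

    genes: list[str]
    edges: pd.DataFrame
    baseline: np.ndarray
    noise_sd: float = 0.0
    stable: bool = True
    allow_self_edges: bool = False

    def __post_init__(self) -> None:
        idx = {g: i for i, g in enumerate(self.genes)}
        missing = (set(self.edges["regulator"]) | set(self.edges["target"])) - set(idx)
        if missing:
            raise ValueError(f"edge genes missing from gene list: {sorted(missing)}")
        if not self.allow_self_edges and (
            (self.edges["regulator"] == self.edges["target"]).any()
        ):
            raise ValueError("self-edges present but allow_self_edges is False")
        if self.stable and self.edges.shape[0] and spectral_radius(self.weight_matrix()) >= 1:
            raise ValueError("weight matrix spectral radius >= 1 for a stable network")

    def weight_matrix(self) -> np.ndarray:
        """W[i, j] = weight of edge gene_i -> gene_j."""
        idx = {g: i for i, g in enumerate(self.genes)}
        W = np.zeros((len(self.genes), len(self.genes)))
        for reg, tgt, w in self.edges[["regulator", "target", "weight"]].itertuples(
            index=False
        ):
            W[idx[reg], idx[tgt]] = w
        return W


def spectral_radius(W: np.ndarray) -> float:
    if W.size == 0:
        return 0.0
    return float(np.abs(np.linalg.eigvals(W)).max())


def random_grn(
    n_genes: int = 30,
    n_regulators: int = 5,
    targets_per_regulator: int = 6,
    weight_range: tuple[float, float] = (0.3, 0.6),
    baseline_range: tuple[float, float] = (2.0, 6.0),
    noise_sd: float = 0.0,
    seed: int = 0,
) -> GroundTruthGrn:
    """Draw a sparse stable truth network with root regulators.

    Regulators are root nodes (no incoming edges), so the weight matrix is
    nilpotent-by-blocks and trivially stable; edge signs are random.
    """
    rng = np.random.default_rng(seed)
    genes = [f"g{j:03d}" for j in range(n_genes)]
    regulators = genes[:n_regulators]
    targets = genes[n_regulators:]
    rows = []
    for reg in regulators:
        chosen = rng.choice(targets, size=min(targets_per_regulator, len(targets)), replace=False)
        for tgt in chosen:
            w = rng.uniform(*weight_range) * rng.choice([-1.0, 1.0])
            rows.append((reg, tgt, w))
    edges = pd.DataFrame(rows, columns=["regulator", "target", "weight"])
    baseline = rng.uniform(*baseline_range, size=n_genes)
    return GroundTruthGrn(genes=genes, edges=edges, baseline=baseline, noise_sd=noise_sd)


def simulate_grn_expression(
    truth: GroundTruthGrn,
    n_cells: int,
    seed: int = 0,
    jitter_sd: float = 1.0,
    jitter_mode: str = "root",
) -> ad.AnnData:
    """Sample continuous expression from the linear structural model.

    Per cell, a jitter vector eps is drawn (on root genes only in ``root``
    mode, on every gene in ``all`` mode) and propagated to the fixed point
    d = (I - W')^-1 eps; expression is baseline + d plus observation noise
    of sd ``truth.noise_sd``.  With no edges and no noise every cell equals
    the baseline exactly when ``jitter_sd`` is 0.
    """
    if not truth.stable:
        raise ValueError("expression simulation requires a stable truth network")
    if jitter_mode not in ("root", "all"):
        raise ValueError("jitter_mode must be 'root' or 'all'")
    rng = np.random.default_rng(seed)
    W = truth.weight_matrix()
    p = len(truth.genes)
    eps = rng.normal(0.0, jitter_sd, size=(n_cells, p))
    if jitter_mode == "root":
        has_incoming = W.any(axis=0)
        eps[:, has_incoming] = 0.0
    # d' = W' d + eps  per cell:  d = eps (I - W)^-1 on the right
    d = np.linalg.solve((np.eye(p) - W).T, eps.T).T
    x = truth.baseline[None, :] + d
    if truth.noise_sd > 0:
        x = x + rng.normal(0.0, truth.noise_sd, size=x.shape)
    return ad.AnnData(
        X=x,
        obs=pd.DataFrame(index=[f"grn_cell_{i:05d}" for i in range(n_cells)]),
        var=pd.DataFrame(index=list(truth.genes)),
    )


def simulate_ko_expression(
    truth: GroundTruthGrn,
    ko_genes: tuple[str, ...],
    n_cells: int,
    seed: int = 0,
    jitter_sd: float = 1.0,
    jitter_mode: str = "root",
) -> ad.AnnData:
    """Sample expression from the truth network with genes knocked out.

    The KO genes are clamped to zero expression (deviation -baseline) and
    their shifts propagate through the structural model exactly as in
    :func:`simulate_grn_expression`; per-cell jitter and observation noise
    are drawn the same way.  Serves as the synthetic "experimental"
    knockout against which in-silico propagation is compared.
    """
    wt = simulate_grn_expression(
        truth, n_cells, seed=seed, jitter_sd=jitter_sd, jitter_mode=jitter_mode
    )
    idx = {g: i for i, g in enumerate(truth.genes)}
    ko_idx = [idx[g] for g in ko_genes if g in idx]
    free = [i for i in range(len(truth.genes)) if i not in set(ko_idx)]
    W = truth.weight_matrix()
    Wt = W.T
    X = np.asarray(wt.X, dtype=float)
    shift = np.zeros_like(X)
    shift[:, ko_idx] = -X[:, ko_idx]
    A = Wt[np.ix_(free, free)]
    b = (Wt[np.ix_(free, ko_idx)] @ shift[:, ko_idx].T).T
    shift[:, free] = np.linalg.solve(np.eye(len(free)) - A, b.T).T
    out = wt.copy()
    out.X = X + shift
    return out


def to_counts(adata: ad.AnnData, depth: float = 20.0, seed: int = 0) -> ad.AnnData:
    """Convert continuous expression to Poisson UMI counts (rates floored at 0)."""
    rng = np.random.default_rng(seed)
    rate = np.clip(np.asarray(adata.X, dtype=float), 0.0, None)
    out = adata.copy()
    out.X = rng.poisson(rate * depth / max(rate.mean(), 1e-12)).astype(np.int64)
    return out


def simulate_trajectory(
    n_cells: int = 600,
    n_genes: int = 150,
    n_dynamic: int = 30,
    depth: float = 2000.0,
    dynamic_fold: float = 6.0,
    seed: int = 0,
) -> ad.AnnData:
    """Cells ordered along a 1-D pseudotime with planted dynamic genes.

    The first ``n_dynamic`` genes ramp log-linearly by ``dynamic_fold``
    across pseudotime (half up, half down); the rest are flat.  Counts are
    Poisson at an average per-cell depth of ``depth``.  ``obs['pseudotime']``
    carries the true ordering in [0, 1].
    """
    rng = np.random.default_rng(seed)
    t = np.sort(rng.random(n_cells))
    base = rng.lognormal(0.0, 0.5, size=n_genes)
    log_fc = np.zeros(n_genes)
    log_fc[: n_dynamic // 2] = np.log(dynamic_fold)
    log_fc[n_dynamic // 2 : n_dynamic] = -np.log(dynamic_fold)
    rate = base[None, :] * np.exp(t[:, None] * log_fc[None, :])
    rate *= depth / rate.sum(axis=1, keepdims=True)
    X = rng.poisson(rate).astype(np.int64)
    obs = pd.DataFrame(
        {"pseudotime": t}, index=[f"traj_cell_{i:05d}" for i in range(n_cells)]
    )
    var = pd.DataFrame(
        {"is_dynamic": np.arange(n_genes) < n_dynamic},
        index=[f"dyn_gene_{g:04d}" for g in range(n_genes)],
    )
    return ad.AnnData(X=X, obs=obs, var=var)
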