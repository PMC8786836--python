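"""Gene-regulatory-network inference from co-accessibility and expression.

The chain is: sample low-overlapping aggregates of cells in a reduced
space; correlate aggregate-level peak accessibility within a genomic
distance window to obtain co-accessible peak pairs; assemble a base GRN by
linking peaks to genes through TSS overlap or co-accessibility with a TSS
peak and reading candidate regulators off the motif hits in linked peaks;
refine per cluster with bagging ridge regression and prune edges by
p-value, weight and cluster-marker membership; then compute network
statistics and rank regulators against a focus gene set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import sparse as sp
from scipy import stats
from sklearn.linear_model import Ridge
from sklearn.neighbors import NearestNeighbors
from statsmodels.stats.multitest import multipletests


@dataclass
class CoaccessConfig:
    k: int = 100  # cells per aggregate
    n_iterations: int = 500
    overlap_cutoff: float = 0.8
    max_distance: int = 250_000
    fdr_max: float = 1e-10
    variability_min: float = 0.35  # variance quantile below which peaks are dropped
    corr_min: float = 0.5

    def __post_init__(self) -> None:
        if not (0 < self.overlap_cutoff <= 1):
            raise ValueError("overlap_cutoff must be in (0, 1]")
        if self.k < 1:
            raise ValueError("k must be >= 1")


def sample_aggregates(
    coords: np.ndarray,
    config: CoaccessConfig,
    seed: int = 0,
) -> list[np.ndarray]:
    """Sample low-overlapping kNN aggregates of cells.

    Up to ``n_iterations`` random seed cells are drawn; each candidate
    aggregate is the seed plus its k-1 nearest neighbors, accepted iff its
    overlap fraction |A intersect B| / k with every accepted aggregate is
    at most ``overlap_cutoff``.
    """
    X = np.asarray(coords, dtype=float)
    n = X.shape[0]
    if n < config.k:
        raise ValueError(f"need at least k={config.k} cells, got {n}")
    rng = np.random.default_rng(seed)
    seeds = rng.choice(n, size=min(config.n_iterations, n), replace=config.n_iterations > n)
    nn = NearestNeighbors(n_neighbors=config.k).fit(X)
    _, idx = nn.kneighbors(X[seeds])
    accepted: list[np.ndarray] = []
    accepted_sets: list[set[int]] = []
    for cand in idx:
        cset = set(int(i) for i in cand)
        if all(
            len(cset & prev) / config.k <= config.overlap_cutoff
            for prev in accepted_sets
        ):
            accepted.append(np.sort(cand))
            accepted_sets.append(cset)
    return accepted


def aggregate_accessibility(
    peak_counts, aggregates: list[np.ndarray], scale: float = 1e4
) -> np.ndarray:
    """Sum counts within each aggregate, rescale per aggregate to ``scale``
    and log2(x+1)-transform; returns aggregates x peaks."""
    X = peak_counts.X if hasattr(peak_counts, "X") else peak_counts
    X = sp.csr_matrix(X) if not sp.issparse(X) else X.tocsr()
    sums = np.vstack([np.asarray(X[a].sum(axis=0)).ravel() for a in aggregates])
    totals = sums.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        norm = np.where(totals > 0, sums * scale / totals, 0.0)
    return np.log2(norm + 1.0)


def compute_coaccessibility(
    peak_counts,
    aggregates: list[np.ndarray],
    peaks: pd.DataFrame,
    config: CoaccessConfig,
) -> pd.DataFrame:
    """Correlate aggregate accessibility of nearby peak pairs.

    Pairs are peaks on the same chromosome whose midpoints lie within
    ``max_distance``.  Pearson correlations get p-values from the t
    statistic (df = #aggregates - 2), BH-adjusted across tested pairs.
    Retained pairs need FDR < ``fdr_max``, both peaks above the
    ``variability_min`` variance quantile, and correlation >=
    ``corr_min``.  The returned table contains both orientations of every
    retained pair.
    """
    if len(aggregates) < 3:
        raise ValueError("need at least 3 aggregates")
    A = aggregate_accessibility(peak_counts, aggregates)
    n_agg, n_peaks = A.shape
    if len(peaks) != n_peaks:
        raise ValueError("peak table does not match the count matrix")

    variances = A.var(axis=0, ddof=1)
    # variability_min <= 0 disables the variance filter; otherwise peaks at
    # or below the quantile are removed ("low variability" exclusion)
    var_threshold = (
        -np.inf
        if config.variability_min <= 0
        else np.quantile(variances, config.variability_min)
    )
    mid = ((peaks["start"].to_numpy() + peaks["end"].to_numpy()) // 2).astype(np.int64)
    chrom = peaks["chrom"].to_numpy()
    names = (
        peaks["name"].to_numpy() if "name" in peaks else peaks.index.to_numpy()
    )

    pairs_i, pairs_j = [], []
    order = np.lexsort((mid, chrom))
    for c in pd.unique(chrom):
        idx = order[chrom[order] == c]
        pos = mid[idx]
        for a in range(len(idx)):
            b = a + 1
            while b < len(idx) and pos[b] - pos[a] <= config.max_distance:
                pairs_i.append(idx[a])
                pairs_j.append(idx[b])
                b += 1
    if not pairs_i:
        return pd.DataFrame(
            columns=["peak1", "peak2", "correlation", "p_value", "fdr"]
        )

    Ac = A - A.mean(axis=0)
    sd = Ac.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        Z = np.where(sd > 0, Ac / sd, 0.0)
    i = np.asarray(pairs_i)
    j = np.asarray(pairs_j)
    r = (Z[:, i] * Z[:, j]).sum(axis=0) / (n_agg - 1)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n_agg - 2) / np.maximum(1 - r**2, 1e-300))
    p = 2 * stats.t.sf(np.abs(t), df=n_agg - 2)
    fdr = multipletests(p, method="fdr_bh")[1]

    keep = (
        (fdr < config.fdr_max)
        & (variances[i] > var_threshold)
        & (variances[j] > var_threshold)
        & (r >= config.corr_min)
    )
    half = pd.DataFrame(
        {
            "peak1": names[i[keep]],
            "peak2": names[j[keep]],
            "correlation": r[keep],
            "p_value": p[keep],
            "fdr": fdr[keep],
        }
    )
    flipped = half.rename(columns={"peak1": "peak2", "peak2": "peak1"})
    return (
        pd.concat([half, flipped[half.columns]], ignore_index=True)
        .sort_values(["peak1", "peak2"])
        .reset_index(drop=True)
    )


# --- base GRN ---------------------------------------------------------------

@dataclass
class BaseGrn:
    """Candidate regulator sets per target gene, with the peak-gene links
    that produced them."""

    candidates: dict[str, set[str]]
    links: pd.DataFrame  # gene, peak, link_type, coaccessibility
    genes_without_tss_peak: list[str] = field(default_factory=list)


def assemble_base_grn(
    coaccess: pd.DataFrame,
    peaks: pd.DataFrame,
    tss_table: pd.DataFrame,
    motif_hits: pd.DataFrame,
    tf_map: dict[str, list[str]],
    coaccess_min: float = 0.5,
) -> BaseGrn:
    """Assemble candidate regulators per gene from peaks, co-accessibility
    and motif hits.

    A peak is linked to a gene iff it overlaps the gene's TSS (link
    strength 1) or has co-accessibility >= ``coaccess_min`` with a TSS peak
    of that gene.  Candidate regulators of a gene are the TFs (via
    ``tf_map``: motif -> TF gene names) whose motifs hit any linked peak.
    Genes with no TSS peak get no candidates and are counted.
    """
    names = peaks["name"].to_numpy() if "name" in peaks else peaks.index.to_numpy()
    starts = peaks["start"].to_numpy()
    ends = peaks["end"].to_numpy()
    chroms = peaks["chrom"].to_numpy()

    tss_peaks: dict[str, list[str]] = {}
    for row in tss_table.itertuples(index=False):
        mask = (chroms == row.chrom) & (starts <= row.tss) & (row.tss < ends)
        tss_peaks[row.gene] = [str(n) for n in names[mask]]

    co_by_peak: dict[str, list[tuple[str, float]]] = {}
    for p1, p2, r in coaccess[["peak1", "peak2", "correlation"]].itertuples(index=False):
        co_by_peak.setdefault(str(p1), []).append((str(p2), float(r)))

    hit_motifs = {
        str(pk): [m for m in motif_hits.columns if motif_hits.at[pk, m]]
        for pk in motif_hits.index
    }

    candidates: dict[str, set[str]] = {}
    rows = []
    missing = []
    for gene, gene_tss_peaks in tss_peaks.items():
        linked: dict[str, tuple[str, float]] = {}
        for pk in gene_tss_peaks:
            linked[pk] = ("tss", 1.0)
        for pk in gene_tss_peaks:
            for other, r in co_by_peak.get(pk, []):
                if r >= coaccess_min and other not in linked:
                    linked[other] = ("coaccessible", r)
        if not gene_tss_peaks:
            missing.append(gene)
        regs: set[str] = set()
        for pk, (kind, strength) in linked.items():
            rows.append((gene, pk, kind, strength))
            for m in hit_motifs.get(pk, []):
                regs.update(tf_map.get(m, []))
        regs.discard(gene)
        candidates[gene] = regs
    links = pd.DataFrame(rows, columns=["gene", "peak", "link_type", "coaccessibility"])
    return BaseGrn(candidates=candidates, links=links, genes_without_tss_peak=missing)


# --- cluster GRN fitting ----------------------------------------------------

@dataclass
class GrnFitConfig:
    alpha: float = 10.0  # ridge penalty
    n_bags: int = 20
    bootstrap: bool = True
    prune_p: float = 0.001
    prune_w: float = 0.005


@dataclass
class ClusterGrn:
    cluster: str
    edges: pd.DataFrame  # regulator, target, weight, p_value, retained
    config: GrnFitConfig

    def retained_edges(self) -> pd.DataFrame:
        return self.edges[self.edges["retained"]].reset_index(drop=True)


def _bagged_ridge(
    X: np.ndarray, y: np.ndarray, config: GrnFitConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Mean coefficient and one-sample t-test p-value across bags."""
    n = X.shape[0]
    coefs = np.empty((config.n_bags, X.shape[1]))
    for b in range(config.n_bags):
        idx = rng.integers(0, n, size=n) if config.bootstrap else np.arange(n)
        model = Ridge(alpha=config.alpha, fit_intercept=False)
        model.fit(X[idx], y[idx])
        coefs[b] = model.coef_
    w = coefs.mean(axis=0)
    if config.n_bags < 2:
        return w, np.ones(X.shape[1])
    # two-sided t-test of the mean bagged coefficient against zero, using the
    # across-bag sd as the bootstrap standard error of the coefficient (the
    # across-bag spread estimates sampling variability, so it is not divided
    # by sqrt(n_bags); that keeps null p-values near uniform)
    se = coefs.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, np.abs(w) / se, np.inf)
    p = 2 * stats.t.sf(t, df=config.n_bags - 1)
    return w, np.where(np.isnan(p), 1.0, p)


def fit_cluster_grn(
    expression: pd.DataFrame,
    clusters: np.ndarray | pd.Series,
    base: BaseGrn | dict[str, set[str]],
    config: GrnFitConfig | None = None,
    marker_genes: dict[str, set[str]] | None = None,
    seed: int = 0,
) -> dict[str, ClusterGrn]:
    """Per-cluster bagging-ridge refinement of the base GRN.

    For each cluster and each target gene, the target's (centered)
    expression is ridge-regressed on its candidate regulators over that
    cluster's cells, bagged ``n_bags`` times over bootstrap resamples of
    the cells.  Edge weight = mean bagged coefficient; p-value = two-sided
    one-sample t-test of the bagged coefficients against 0.  Edges survive
    pruning iff p <= prune_p, |weight| > prune_w and (when ``marker_genes``
    is given) the regulator is in that cluster's marker set; surviving
    regulator sets are refit to give the final weights.
    """
    config = config or GrnFitConfig()
    candidates = base.candidates if isinstance(base, BaseGrn) else base
    labels = np.asarray(clusters).astype(str)
    rng = np.random.default_rng(seed)
    out: dict[str, ClusterGrn] = {}
    for cl in pd.unique(labels):
        cells = expression.loc[labels == cl]
        Xc = cells - cells.mean(axis=0)
        rows = []
        for target, regs in candidates.items():
            regs = sorted(r for r in regs if r in Xc.columns and r != target)
            if not regs or target not in Xc.columns:
                continue
            if len(cells) <= len(regs):
                warnings.warn(
                    f"cluster {cl}: {len(cells)} cells for {len(regs)} regulators of {target}",
                    stacklevel=2,
                )
            X = Xc[regs].to_numpy()
            y = Xc[target].to_numpy()
            w, p = _bagged_ridge(X, y, config, rng)
            keep = (p <= config.prune_p) & (np.abs(w) > config.prune_w)
            if marker_genes is not None:
                in_markers = np.array(
                    [r in marker_genes.get(cl, set()) for r in regs]
                )
                keep &= in_markers
            # refit on surviving regulators only
            final_w = dict(zip(regs, w))
            if keep.any() and keep.sum() < len(regs):
                survivors = [r for r, k in zip(regs, keep) if k]
                w2, _ = _bagged_ridge(Xc[survivors].to_numpy(), y, config, rng)
                final_w.update(dict(zip(survivors, w2)))
            for r, wi, pi, ki in zip(regs, w, p, keep):
                rows.append((r, target, final_w[r] if ki else wi, pi, bool(ki)))
        edges = pd.DataFrame(
            rows, columns=["regulator", "target", "weight", "p_value", "retained"]
        )
        out[str(cl)] = ClusterGrn(cluster=str(cl), edges=edges, config=config)
    return out


# --- network statistics and regulator ranking -------------------------------

def network_stats(
    edges: pd.DataFrame,
    expression: pd.DataFrame | None = None,
    clusters: np.ndarray | pd.Series | None = None,
) -> pd.DataFrame:
    """Outdegree, unnormalized directed betweenness centrality and (when
    expression is given) per-cluster expression specificity of each node.

    Specificity of a gene in a cluster = cluster mean expression / median
    over clusters of the cluster means.
    """
    G = nx.DiGraph()
    G.add_edges_from(edges[["regulator", "target"]].itertuples(index=False))
    if G.number_of_nodes() == 0:
        return pd.DataFrame(columns=["node", "outdegree", "betweenness"])
    btw = nx.betweenness_centrality(G, normalized=False)
    stats_df = pd.DataFrame(
        {
            "node": list(G.nodes),
            "outdegree": [G.out_degree(v) for v in G.nodes],
            "betweenness": [btw[v] for v in G.nodes],
        }
    )
    if expression is not None and clusters is not None:
        means = expression.groupby(np.asarray(clusters).astype(str)).mean()
        med = means.median(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            specificity = means / med
        for cl in means.index:
            stats_df[f"specificity_{cl}"] = [
                float(specificity.at[cl, v]) if v in specificity.columns else np.nan
                for v in stats_df["node"]
            ]
    return stats_df


def leiden_partition(G: nx.Graph, resolution: float = 2.0, seed: int = 0) -> dict:
    """Default community partitioner: Leiden modularity via igraph."""
    import igraph
    import leidenalg

    nodes = list(G.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    g = igraph.Graph(
        n=len(nodes),
        edges=[(index[u], index[v]) for u, v in G.edges],
        directed=False,
    )
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=seed,
    )
    return {nodes[i]: m for i, m in enumerate(part.membership)}


@dataclass
class RegulatorRanking:
    ranking: pd.DataFrame  # regulator, n_focus_targets, rank
    subgraph: nx.DiGraph
    communities: dict
    activity: pd.DataFrame | None  # clusters x communities mean expression


def rank_regulators(
    edges: pd.DataFrame,
    focus_genes: set[str],
    top_n: int = 200,
    weight_cutoff: float = 0.01,
    resolution: float = 2.0,
    partitioner=None,
    expression: pd.DataFrame | None = None,
    clusters: np.ndarray | pd.Series | None = None,
    seed: int = 0,
) -> RegulatorRanking:
    """Rank regulators by focus-set intersection and extract the top-n
    subgraph with its community structure.

    Edges below ``weight_cutoff`` are dropped; regulators are ranked by
    |targets intersect focus_genes| descending, ties broken
    lexicographically.  Communities of the induced top-n subgraph come from
    ``partitioner`` (defaults to Leiden at the given resolution).
    Subnetwork activity = mean expression of each community's member genes
    per cluster.
    """
    if not focus_genes:
        raise ValueError("focus gene set must be nonempty")
    strong = edges[edges["weight"].abs() >= weight_cutoff]
    targets_of = strong.groupby("regulator")["target"].agg(set)
    counts = targets_of.apply(lambda s: len(s & set(focus_genes)))
    ranking = (
        pd.DataFrame({"regulator": counts.index, "n_focus_targets": counts.values})
        .sort_values(["n_focus_targets", "regulator"], ascending=[False, True])
        .reset_index(drop=True)
    )
    ranking["rank"] = np.arange(1, len(ranking) + 1)

    top = list(ranking["regulator"].head(top_n))
    G = nx.DiGraph()
    G.add_nodes_from(top)
    in_top = set(top)
    for r, t, w in strong[["regulator", "target", "weight"]].itertuples(index=False):
        if r in in_top and t in in_top:
            G.add_edge(r, t, weight=w)

    part = partitioner or leiden_partition
    communities = part(G.to_undirected(), resolution=resolution, seed=seed) if G.number_of_nodes() else {}

    activity = None
    if expression is not None and clusters is not None and communities:
        means = expression.groupby(np.asarray(clusters).astype(str)).mean()
        cols = {}
        for comm in sorted(set(communities.values())):
            members = [v for v, m in communities.items() if m == comm and v in means.columns]
            cols[f"community_{comm}"] = (
                means[members].mean(axis=1) if members else pd.Series(0.0, index=means.index)
            )
        activity = pd.DataFrame(cols)
    return RegulatorRanking(
        ranking=ranking, subgraph=G, communities=communities, activity=activity
    )
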