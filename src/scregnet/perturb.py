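"""In-silico TF knockout, atlas projection/classification, compositional
abundance inference and pseudotime staging.

The knockout simulation clamps the knocked-out genes' expression shift at
minus their baseline and propagates the shift through the signed GRN for a
fixed depth; on the subsystem of unclamped genes this is the truncated
geometric series of the weight matrix and converges to the analytic
(I - W'_ff)^-1 fixed point when the network is stable.  Perturbed cells are
compared to the atlas by PCA projection plus k-nearest-neighbor plurality
voting, cluster abundances get asymptotic quasi-Poisson confidence
intervals, and genotypes are staged against atlas pseudotime bins by rank
correlation of dynamic-gene pseudobulks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.neighbors import NearestNeighbors


# --- in-silico knockout -----------------------------------------------------

@dataclass
class KoConfig:
    ko_genes: tuple[str, ...]
    depth: int = 5
    clipping: str = "nonneg"  # {none, nonneg, observed_range}

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.clipping not in ("none", "nonneg", "observed_range"):
            raise ValueError(f"unknown clipping mode {self.clipping!r}")


def simulate_ko(
    edges: pd.DataFrame,
    baseline: pd.DataFrame,
    config: KoConfig,
) -> pd.DataFrame:
    """Propagate a knockout through the network for ``config.depth`` steps.

    ``edges`` carries (regulator, target, weight); ``baseline`` is the
    per-cell per-gene expression the deltas are measured against.  The
    initial shift is -baseline on the KO genes and 0 elsewhere; each step
    applies delta[g] <- sum_r W[r -> g] delta[r] with the KO genes clamped
    back to -baseline.  Returns the per-cell per-gene delta matrix;
    clipping guarantees baseline + delta stays in the requested range.  KO
    genes absent from the network give a zero-delta result with a warning.
    """
    genes = list(baseline.columns)
    idx = {g: i for i, g in enumerate(genes)}
    present = [g for g in config.ko_genes if g in idx]
    missing = [g for g in config.ko_genes if g not in idx]
    if missing:
        warnings.warn(f"KO genes absent from the network: {missing}", stacklevel=2)
    if not present:
        return pd.DataFrame(
            np.zeros(baseline.shape), index=baseline.index, columns=genes
        )

    W = np.zeros((len(genes), len(genes)))
    for r, t, w in edges[["regulator", "target", "weight"]].itertuples(index=False):
        if r in idx and t in idx:
            W[idx[r], idx[t]] = w

    B = baseline.to_numpy(dtype=float)
    ko_idx = [idx[g] for g in present]
    delta = np.zeros_like(B)
    delta[:, ko_idx] = -B[:, ko_idx]
    for _ in range(config.depth):
        delta = delta @ W
        delta[:, ko_idx] = -B[:, ko_idx]

    simulated = B + delta
    if config.clipping == "nonneg":
        simulated = np.maximum(simulated, 0.0)
    elif config.clipping == "observed_range":
        lo = B.min(axis=0)
        hi = B.max(axis=0)
        simulated = np.clip(simulated, lo, hi)
    delta = simulated - B
    return pd.DataFrame(delta, index=baseline.index, columns=genes)


def ko_fixed_point(
    edges: pd.DataFrame, baseline: pd.DataFrame, ko_genes: tuple[str, ...]
) -> pd.DataFrame:
    """Analytic infinite-depth knockout shift.

    With KO genes clamped at -baseline, the free genes converge to
    delta_f = (I - W'_ff)^-1 W'_fk (-baseline_k) when the free-free block
    is stable.
    """
    genes = list(baseline.columns)
    idx = {g: i for i, g in enumerate(genes)}
    ko_idx = [idx[g] for g in ko_genes if g in idx]
    free = [i for i in range(len(genes)) if i not in set(ko_idx)]
    W = np.zeros((len(genes), len(genes)))
    for r, t, w in edges[["regulator", "target", "weight"]].itertuples(index=False):
        if r in idx and t in idx:
            W[idx[r], idx[t]] = w
    B = baseline.to_numpy(dtype=float)
    delta = np.zeros_like(B)
    delta[:, ko_idx] = -B[:, ko_idx]
    Wt = W.T
    A = Wt[np.ix_(free, free)]
    b = (Wt[np.ix_(free, ko_idx)] @ (-B[:, ko_idx]).T).T
    delta[:, free] = np.linalg.solve(np.eye(len(free)) - A, b.T).T
    return pd.DataFrame(delta, index=baseline.index, columns=genes)


def compare_sim_vs_exp(
    sim_delta: pd.Series, exp_log2fc: pd.Series
) -> tuple[float, float, pd.DataFrame]:
    """Spearman rank correlation between simulated per-gene shifts and
    experimental log fold changes on the shared gene universe."""
    shared = sim_delta.index.intersection(exp_log2fc.index)
    if len(shared) < 3:
        raise ValueError("need at least 3 shared genes")
    a = sim_delta.loc[shared].to_numpy(dtype=float)
    b = exp_log2fc.loc[shared].to_numpy(dtype=float)
    if np.all(a == a[0]) or np.all(b == b[0]):
        raise ValueError("constant vector: rank correlation undefined")
    rho, p = stats.spearmanr(a, b)
    table = pd.DataFrame({"sim_delta": a, "exp_log2fc": b}, index=shared)
    return float(rho), float(p), table


# --- projection / classification -------------------------------------------

@dataclass
class ProjectionResult:
    """Per-query-cell atlas coordinates, plurality label, label-probability
    vector (neighbor vote fractions) and averaged embedding position."""

    labels: pd.Series
    probabilities: pd.DataFrame  # cells x clusters, rows sum to 1
    embedding: pd.DataFrame | None
    k: int

    def to_frame(self) -> pd.DataFrame:
        out = self.probabilities.add_prefix("p_")
        out.insert(0, "label", self.labels)
        if self.embedding is not None:
            out[["x", "y"]] = self.embedding.iloc[:, :2]
        return out


def classify_knn(
    query_coords: np.ndarray,
    atlas_coords: np.ndarray,
    atlas_labels,
    atlas_embedding: np.ndarray | None = None,
    k: int = 50,
    query_index=None,
) -> ProjectionResult:
    """Plurality-vote classification of query cells against the atlas.

    Each query cell's k nearest atlas cells (Euclidean distance) vote;
    probabilities are vote fractions, the label is the plurality winner
    (ties broken toward the lexicographically smallest cluster id), and
    the embedding position is the mean of the neighbors' embedding
    coordinates.
    """
    atlas_coords = np.asarray(atlas_coords, dtype=float)
    if k > atlas_coords.shape[0]:
        raise ValueError(f"k={k} exceeds atlas size {atlas_coords.shape[0]}")
    labels = np.asarray(atlas_labels).astype(str)
    classes = np.array(sorted(pd.unique(labels)))
    nn = NearestNeighbors(n_neighbors=k).fit(atlas_coords)
    _, idx = nn.kneighbors(np.asarray(query_coords, dtype=float))

    votes = np.zeros((idx.shape[0], len(classes)))
    class_pos = {c: j for j, c in enumerate(classes)}
    for j, c in enumerate(classes):
        votes[:, j] = (labels[idx] == c).sum(axis=1)
    probs = votes / k
    # argmax returns the first (lexicographically smallest) class on ties
    winner = classes[probs.argmax(axis=1)]

    if query_index is None:
        query_index = pd.RangeIndex(idx.shape[0])
    embedding = None
    if atlas_embedding is not None:
        emb = np.asarray(atlas_embedding, dtype=float)
        embedding = pd.DataFrame(
            emb[idx].mean(axis=1),
            index=query_index,
            columns=[f"emb_{d}" for d in range(emb.shape[1])],
        )
    return ProjectionResult(
        labels=pd.Series(winner, index=query_index, name="label"),
        probabilities=pd.DataFrame(probs, index=query_index, columns=classes),
        embedding=embedding,
        k=k,
    )


# --- compositional abundance ------------------------------------------------

@dataclass
class AbundanceEstimate:
    table: pd.DataFrame  # cluster, log_fc, ci_lower, ci_upper, dispersion, flagged
    min_count: int


def fit_quasipoisson(
    counts: np.ndarray,
    design: np.ndarray,
    offset_log: np.ndarray,
    coef_index: int = 1,
    force_phi: float | None = None,
) -> tuple[float, float, float]:
    """Quasi-Poisson log-link fit; returns (estimate, se, dispersion).

    The Poisson GLM is fit by IRLS (statsmodels) and the Pearson X^2 / df
    dispersion rescales the standard errors; ``force_phi=1`` reduces to the
    plain Poisson fit.  ``coef_index`` selects the coefficient of interest
    in the design (default: the column after the intercept).
    """
    model = sm.GLM(
        np.asarray(counts, dtype=float),
        np.asarray(design, dtype=float),
        family=sm.families.Poisson(),
        offset=np.asarray(offset_log, dtype=float),
    )
    res = model.fit(scale="X2") if force_phi is None else model.fit(scale=force_phi)
    return float(res.params[coef_index]), float(res.bse[coef_index]), float(res.scale)


def abundance_ci(
    probabilities: pd.DataFrame,
    genotype: pd.Series,
    replicate: pd.Series,
    batch: pd.Series | None = None,
    k: int = 50,
    min_count: int = 100,
    reference_genotype: str | None = None,
    force_phi: float | None = None,
) -> AbundanceEstimate:
    """Quasi-Poisson confidence intervals for per-cluster abundance shifts.

    Per cluster and replicate, the response is the summed assignment
    probability of that replicate's cells times the neighbor count ``k``,
    rounded to whole numbers.  A Poisson log-link GLM with genotype (and
    optional batch) covariates and offset log(replicate total cells) is
    fit; the dispersion phi = Pearson X^2 / df rescales the standard
    errors (quasi-Poisson), giving estimate +/- 1.96 se CIs on the natural
    log scale.  Clusters with fewer than ``min_count`` total weighted cells
    are flagged; a genotype with zero cells in a cluster yields a flagged
    row with NaN estimates rather than an infinite number.
    """
    genotype = genotype.astype(str)
    levels = sorted(genotype.unique())
    if reference_genotype is None:
        reference_genotype = levels[0]
    other = [g for g in levels if g != reference_genotype]
    if len(other) != 1:
        raise ValueError("exactly two genotype levels are required")

    rep_tab = pd.DataFrame({"replicate": replicate.astype(str), "genotype": genotype})
    if batch is not None:
        rep_tab["batch"] = batch.astype(str)
    rep_info = rep_tab.groupby("replicate").agg("first")
    rep_totals = rep_tab.groupby("replicate").size()

    rows = []
    for cluster in probabilities.columns:
        counts = (
            (probabilities[cluster] * k)
            .groupby(rep_tab["replicate"].values)
            .sum()
            .round()
            .astype(int)
        )
        counts = counts.reindex(rep_info.index, fill_value=0)
        total_cells = counts.sum() / k
        geno_counts = counts.groupby(rep_info["genotype"]).sum()
        flagged = total_cells < min_count
        if (geno_counts == 0).any():
            rows.append((cluster, np.nan, np.nan, np.nan, np.nan, True))
            continue
        X = pd.DataFrame({"intercept": 1.0}, index=rep_info.index)
        X["genotype"] = (rep_info["genotype"] == other[0]).astype(float)
        if batch is not None:
            for b in sorted(rep_info["batch"].unique())[1:]:
                X[f"batch_{b}"] = (rep_info["batch"] == b).astype(float)
        est, se, phi = fit_quasipoisson(
            counts.to_numpy(),
            X.to_numpy(),
            np.log(rep_totals.reindex(rep_info.index).to_numpy(dtype=float)),
            coef_index=list(X.columns).index("genotype"),
            force_phi=force_phi,
        )
        rows.append(
            (cluster, est, est - 1.96 * se, est + 1.96 * se, phi, bool(flagged))
        )
    table = pd.DataFrame(
        rows,
        columns=["cluster", "log_fc", "ci_lower", "ci_upper", "dispersion", "flagged"],
    )
    return AbundanceEstimate(table=table, min_count=min_count)


def null_coverage_simulation(
    n_sims: int = 500,
    n_replicates: int = 10,
    mean_count: float = 200.0,
    replicate_total: float = 1000.0,
    overdispersion: float = 1.0,
    seed: int = 0,
) -> float:
    """Fraction of null simulations whose 95% quasi-Poisson CI covers 0.

    Two genotypes with ``n_replicates`` replicates each draw per-replicate
    cluster counts with identical means (true log fold change 0), Poisson
    for ``overdispersion`` 1 or gamma-Poisson otherwise; each simulated
    dataset is fit with :func:`fit_quasipoisson` and coverage of the 1.96
    Wald interval is tallied.
    """
    rng = np.random.default_rng(seed)
    n = 2 * n_replicates
    design = np.column_stack([np.ones(n), np.repeat([0.0, 1.0], n_replicates)])
    offset = np.log(np.full(n, replicate_total))
    covered = 0
    for _ in range(n_sims):
        if overdispersion > 1:
            lam = rng.gamma(
                mean_count / (overdispersion - 1), overdispersion - 1, size=n
            )
            y = rng.poisson(lam)
        else:
            y = rng.poisson(mean_count, size=n)
        est, se, _ = fit_quasipoisson(y, design, offset)
        covered += (est - 1.96 * se) <= 0.0 <= (est + 1.96 * se)
    return covered / n_sims


def thymus_filter(
    result: ProjectionResult,
    expression,
    score_clusters: set[str],
    sentinel_gene: str = "Il7",
    min_score: float = 0.8,
) -> pd.Index:
    """Retain cells with summed probability over ``score_clusters`` at
    least ``min_score`` (inclusive) and nonzero sentinel-gene counts."""
    var_names = (
        list(expression.var_names) if hasattr(expression, "var_names") else list(expression.columns)
    )
    if sentinel_gene not in var_names:
        raise KeyError(f"sentinel gene {sentinel_gene!r} absent from matrix")
    cols = [c for c in result.probabilities.columns if c in score_clusters]
    score = result.probabilities[cols].sum(axis=1)
    if hasattr(expression, "X"):
        col = expression[:, sentinel_gene].X
        counts = np.asarray(col.todense()).ravel() if hasattr(col, "todense") else np.asarray(col).ravel()
        counts = pd.Series(counts, index=result.probabilities.index)
    else:
        counts = expression[sentinel_gene]
    keep = (score >= min_score) & (counts > 0)
    return result.probabilities.index[keep]


# --- pseudotime staging -----------------------------------------------------

def bin_pseudotime(pseudotime: np.ndarray, n_bins: int = 20) -> np.ndarray:
    """Assign cells to contiguous equal-count pseudotime bins.

    Bins follow the pseudotime order (ties broken by stable input order)
    and differ in size by at most one, larger bins first.  Bin index is
    monotone non-decreasing in pseudotime.
    """
    t = np.asarray(pseudotime)
    n = len(t)
    if n_bins > n:
        raise ValueError(f"n_bins={n_bins} exceeds n_cells={n}")
    order = np.argsort(t, kind="stable")
    bins = np.empty(n, dtype=int)
    for b, chunk in enumerate(np.array_split(order, n_bins)):
        bins[chunk] = b
    return bins


def dynamic_genes(
    counts: np.ndarray,
    pseudotime: np.ndarray,
    gene_names: list[str],
    n_periods: int = 20,
    min_log2_fc: float = 0.75,
    max_q: float = 0.01,
    epsilon: float = 1.0,
) -> pd.DataFrame:
    """Screen for genes dynamic along pseudotime.

    Cells are split into ``n_periods`` equal-count periods.  Per gene,
    max_fold_change = log2(max period mean + eps) - log2(min period mean +
    eps); the q-value comes from a Kruskal-Wallis across-period location
    test, BH-adjusted.  Genes pass with max_fold_change > ``min_log2_fc``
    and q < ``max_q``; constant genes get q = 1 and never pass.
    """
    X = np.asarray(counts, dtype=float)
    periods = bin_pseudotime(pseudotime, n_periods)
    groups = [X[periods == b] for b in range(n_periods)]
    period_means = np.vstack([g.mean(axis=0) for g in groups])
    max_fc = np.log2(period_means.max(axis=0) + epsilon) - np.log2(
        period_means.min(axis=0) + epsilon
    )
    q_raw = np.ones(X.shape[1])
    p_vals = np.ones(X.shape[1])
    for j in range(X.shape[1]):
        samples = [g[:, j] for g in groups]
        pooled = X[:, j]
        if np.all(pooled == pooled[0]):
            p_vals[j] = 1.0
            continue
        p_vals[j] = stats.kruskal(*samples).pvalue
    q_raw = multipletests_bh(p_vals)
    out = pd.DataFrame(
        {
            "gene": gene_names,
            "max_fold_change": max_fc,
            "p_value": p_vals,
            "q_value": q_raw,
        }
    )
    out["selected"] = (out["max_fold_change"] > min_log2_fc) & (out["q_value"] < max_q)
    return out


def multipletests_bh(p: np.ndarray) -> np.ndarray:
    from statsmodels.stats.multitest import multipletests

    return multipletests(np.asarray(p), method="fdr_bh")[1]


@dataclass
class StageAssignment:
    correlations: pd.DataFrame  # genotypes x bins
    top_bins: dict[str, tuple[int, int]]  # genotype -> two best bins


def stage_correlate(
    genotype_pseudobulks: pd.DataFrame,
    bin_pseudobulks: pd.DataFrame,
    dynamic_set: list[str],
) -> StageAssignment:
    """Stage each genotype against atlas pseudotime bins.

    Pseudobulks are raw-count sums (genes in columns, one row per genotype
    or per bin).  Each profile is rank-transformed over the dynamic gene
    set, then each genotype is Pearson-correlated with each bin; the two
    bins with the largest correlations are that genotype's stage.
    """
    if bin_pseudobulks.shape[0] < 2:
        raise ValueError("need at least 2 pseudotime bins")
    genes = [g for g in dynamic_set if g in genotype_pseudobulks.columns]
    G = genotype_pseudobulks[genes].apply(
        lambda row: stats.rankdata(row), axis=1, result_type="expand"
    )
    B = bin_pseudobulks[genes].apply(
        lambda row: stats.rankdata(row), axis=1, result_type="expand"
    )
    corr = pd.DataFrame(
        np.corrcoef(G.to_numpy(), B.to_numpy())[: len(G), len(G):],
        index=genotype_pseudobulks.index,
        columns=bin_pseudobulks.index,
    )
    top = {
        str(g): tuple(corr.loc[g].nlargest(2).index)
        for g in corr.index
    }
    return StageAssignment(correlations=corr, top_bins=top)
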