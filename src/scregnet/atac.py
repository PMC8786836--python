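"""Chromatin peak geometry, specificity, conservation and motif scoring.

Covers the peak-level feature steps of the scATAC side of the pipeline:
strand-aware promoter/exonic/intronic/distal annotation, iterative-overlap
merging of fixed-width peaks, the tau cluster-specificity index, mean
conservation filtering, chromVAR-style bias-corrected motif deviation
z-scores against GC/accessibility-matched background peaks, and the
motif-gene pairing procedure that matches a transcription factor's motif
activity to its expression within the same TF family.

All intervals are BED-style 0-based half-open.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import sparse as sp


# --- peak annotation -------------------------------------------------------

def promoter_window(tss: int, strand: str, upstream: int = 2000, downstream: int = 100) -> tuple[int, int]:
    """Half-open promoter window around a TSS: [TSS-2000, TSS+100] inclusive
    on + (mirrored on -), converted to half-open coordinates."""
    if strand == "-":
        return tss - downstream, tss + upstream + 1
    return tss - upstream, tss + downstream + 1


def annotate_peaks(
    peaks: pd.DataFrame,
    genes: pd.DataFrame,
    upstream: int = 2000,
    downstream: int = 100,
) -> pd.Series:
    """Label peaks promoter / exonic / intronic / distal, in that precedence.

    ``peaks`` needs chrom/start/end; ``genes`` needs gene, chrom, tss,
    strand, and optionally gene body (start/end) and an ``exons`` column of
    (start, end) lists.  Promoter = any overlap with the strand-aware
    promoter window; exonic = overlap with any exon; intronic = overlap
    with a gene body but no exon; distal = none of these.
    """
    unknown = set(peaks["chrom"]) - set(genes["chrom"])
    if unknown:
        raise ValueError(f"peaks on chromosomes without gene models: {sorted(unknown)}")

    prom: dict[str, IntervalTree] = {}
    exon: dict[str, IntervalTree] = {}
    body: dict[str, IntervalTree] = {}
    for row in genes.itertuples(index=False):
        lo, hi = promoter_window(row.tss, row.strand, upstream, downstream)
        prom.setdefault(row.chrom, IntervalTree()).addi(lo, hi)
        if hasattr(row, "start") and hasattr(row, "end") and not (
            pd.isna(row.start) or pd.isna(row.end)
        ):
            body.setdefault(row.chrom, IntervalTree()).addi(int(row.start), int(row.end))
        if hasattr(row, "exons") and isinstance(row.exons, (list, tuple)):
            for s, e in row.exons:
                exon.setdefault(row.chrom, IntervalTree()).addi(int(s), int(e))

    labels = []
    for row in peaks.itertuples(index=False):
        c, s, e = row.chrom, int(row.start), int(row.end)
        if c in prom and prom[c].overlap(s, e):
            labels.append("promoter")
        elif c in exon and exon[c].overlap(s, e):
            labels.append("exonic")
        elif c in body and body[c].overlap(s, e):
            labels.append("intronic")
        else:
            labels.append("distal")
    return pd.Series(labels, index=peaks.index, name="annotation")


# --- iterative overlap merging --------------------------------------------

def merge_iterative_overlap(
    peaks: pd.DataFrame,
    score_col: str = "score",
    replicate_col: str | None = None,
    min_replicates: int = 1,
) -> pd.DataFrame:
    """Greedy iterative-overlap merge of scored fixed-width peaks.

    Repeatedly keep the remaining peak with the highest normalized
    significance score and discard every peak overlapping it.  With
    ``replicate_col`` set, a retained peak must be supported by at least
    ``min_replicates`` distinct replicates among the input peaks that
    overlap it (itself included).
    """
    df = peaks.reset_index(drop=True)
    order = df[score_col].to_numpy(dtype=float).argsort()[::-1]
    kept: list[int] = []
    trees: dict[str, IntervalTree] = {}
    for i in order:
        c, s, e = df.at[i, "chrom"], int(df.at[i, "start"]), int(df.at[i, "end"])
        if c in trees and trees[c].overlap(s, e):
            continue
        if replicate_col is not None and min_replicates > 1:
            same = df[(df["chrom"] == c) & (df["start"] < e) & (df["end"] > s)]
            if same[replicate_col].nunique() < min_replicates:
                continue
        trees.setdefault(c, IntervalTree()).addi(s, e)
        kept.append(i)
    return df.loc[sorted(kept)].reset_index(drop=True)


# --- tau specificity index -------------------------------------------------

@dataclass
class TauScores:
    tau: np.ndarray  # per peak, NaN where undefined (all-zero peaks)
    x: np.ndarray  # per-peak per-cluster scaled signal, max-normalized to 1
    n_clusters: int


def tau_index(x: np.ndarray) -> TauScores:
    """Tau specificity from a per-peak per-cluster matrix already scaled so
    the per-peak maximum is 1: tau = sum_i (1 - x_i) / (N - 1)."""
    X = np.asarray(x, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need a peaks x clusters matrix with at least 2 clusters")
    N = X.shape[1]
    maxes = X.max(axis=1)
    tau = np.full(X.shape[0], np.nan)
    ok = maxes > 0
    tau[ok] = (1.0 - X[ok]).sum(axis=1) / (N - 1)
    return TauScores(tau=tau, x=X, n_clusters=N)


def tau_from_cluster_means(
    cluster_means: np.ndarray, scale: float = 1e4
) -> TauScores:
    """Tau from raw per-cluster mean accessibility.

    Cluster means are rescaled so each cluster profile sums to ``scale``,
    log2(x+1)-transformed, per-peak max-normalized, then passed to
    :func:`tau_index` (mirrors scaled log2 cluster-averaged accessibility).
    """
    M = np.asarray(cluster_means, dtype=float)  # peaks x clusters
    totals = M.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        scaled = np.where(totals > 0, M * scale / totals, 0.0)
    logged = np.log2(scaled + 1.0)
    maxes = logged.max(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        x = np.where(maxes > 0, logged / maxes, 0.0)
    return tau_index(x)


# --- conservation ----------------------------------------------------------

def conservation_filter(
    peaks: pd.DataFrame,
    scores: pd.DataFrame,
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Retain peaks whose mean per-base conservation is strictly above
    ``threshold``.

    ``scores`` is bedGraph-like (chrom, start, end, score); bases not
    covered count as 0.  Adds a ``mean_conservation`` column.
    """
    by_chrom = {c: g[["start", "end", "score"]].to_numpy() for c, g in scores.groupby("chrom")}
    means = []
    for row in peaks.itertuples(index=False):
        s, e = int(row.start), int(row.end)
        total = 0.0
        for bs, be, val in by_chrom.get(row.chrom, np.empty((0, 3))):
            lo, hi = max(s, int(bs)), min(e, int(be))
            if hi > lo:
                total += val * (hi - lo)
        means.append(total / (e - s))
    out = peaks.copy()
    out["mean_conservation"] = means
    return out[out["mean_conservation"] > threshold].reset_index(drop=True)


def gene_activity_scores(
    peak_counts,
    peaks: pd.DataFrame,
    genes: pd.DataFrame,
    body_upstream: int = 5000,
    distal_window: int = 100_000,
    decay: float = 5000.0,
) -> pd.DataFrame:
    """Simplified approximate per-gene chromatin activity (cells x genes).

    A deliberately simple stand-in for full tile-based gene scoring: peaks
    overlapping the gene body (extended ``body_upstream`` bp upstream,
    strand-aware) contribute their insertion counts with weight 1; distal
    peaks within ``distal_window`` bp of the body contribute with weight
    exp(-distance/decay), distance taken from the peak midpoint to the
    nearest body edge.  Intended for exploratory labeling only; it makes
    no attempt to reproduce any production gene-score model.
    """
    X = peak_counts.X if hasattr(peak_counts, "X") else peak_counts
    X = np.asarray(X.todense() if sp.issparse(X) else X, dtype=float)
    mid = (peaks["start"].to_numpy() + peaks["end"].to_numpy()) // 2
    chrom = peaks["chrom"].to_numpy()
    cols = {}
    for row in genes.itertuples(index=False):
        start = int(getattr(row, "start", row.tss))
        end = int(getattr(row, "end", row.tss + 1))
        if row.strand == "-":
            end += body_upstream
        else:
            start -= body_upstream
        on_chrom = chrom == row.chrom
        d = np.where(
            (mid >= start) & (mid < end),
            0.0,
            np.minimum(np.abs(mid - start), np.abs(mid - end)),
        )
        w = np.where(d == 0.0, 1.0, np.exp(-d / decay))
        w[~on_chrom | (d > distal_window)] = 0.0
        cols[row.gene] = X @ w
    index = (
        list(peak_counts.obs_names)
        if hasattr(peak_counts, "obs_names")
        else pd.RangeIndex(X.shape[0])
    )
    return pd.DataFrame(cols, index=index)


# --- chromVAR-style motif deviations ---------------------------------------

@dataclass
class DeviationScores:
    """Bias-corrected motif deviation z-scores (cells x motifs) with the raw
    deviations and the per-peak background sets used for correction."""

    z: pd.DataFrame
    raw: pd.DataFrame
    background_sets: np.ndarray  # peaks x n_background indices


def _background_sets(
    gc: np.ndarray,
    mean_access: np.ndarray,
    n_background: int,
    rng: np.random.Generator,
    n_bins: int = 10,
) -> np.ndarray:
    """For each peak, sample background peaks from the same GC-decile x
    accessibility-decile bin (with replacement when a bin is thin)."""
    def decile(v: np.ndarray) -> np.ndarray:
        ranks = pd.Series(v).rank(method="first").to_numpy()
        return np.minimum(((ranks - 1) / len(v) * n_bins).astype(int), n_bins - 1)

    bins = decile(gc) * n_bins + decile(mean_access)
    members: dict[int, np.ndarray] = {
        b: np.flatnonzero(bins == b) for b in np.unique(bins)
    }
    n_peaks = len(gc)
    out = np.empty((n_peaks, n_background), dtype=int)
    for j in range(n_peaks):
        pool = members[bins[j]]
        out[j] = rng.choice(pool, size=n_background, replace=True)
    return out


def motif_deviations(
    peak_counts,
    motif_hits: pd.DataFrame,
    gc: np.ndarray,
    n_background: int = 50,
    seed: int = 0,
) -> DeviationScores:
    """Bias-corrected motif accessibility deviations (chromVAR scheme).

    ``peak_counts`` is cells x peaks (array, sparse, or AnnData);
    ``motif_hits`` is a peaks x motifs binary frame.  Expected motif
    accessibility of a cell assumes cell-independent peak usage:
    E[cell, motif] = cell_total * (motif peak totals / grand total).  Raw
    deviation = (observed - expected) / expected; the z-score subtracts the
    mean and divides by the sd of the deviations of ``n_background``
    GC/accessibility-matched background peak sets.  Motifs with zero hits
    yield NaN columns with a warning.
    """
    if hasattr(peak_counts, "X"):
        X = peak_counts.X
        cell_names = list(peak_counts.obs_names)
    else:
        X = peak_counts
        cell_names = [f"cell_{i}" for i in range(X.shape[0])]
    X = np.asarray(X.todense() if sp.issparse(X) else X, dtype=float)
    H = motif_hits.to_numpy(dtype=float)  # peaks x motifs
    n_cells, n_peaks = X.shape
    if H.shape[0] != n_peaks:
        raise ValueError("motif hits must cover the peak set")

    rng = np.random.default_rng(seed)
    peak_totals = X.sum(axis=0)
    cell_totals = X.sum(axis=1)
    grand = peak_totals.sum()
    frac = peak_totals / grand  # expected peak usage, cell-independent

    def deviations(hits: np.ndarray) -> np.ndarray:
        # hits: peaks x m; returns cells x m
        obs = X @ hits
        exp = cell_totals[:, None] * (frac @ hits)[None, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(exp > 0, (obs - exp) / exp, np.nan)

    raw = deviations(H)

    bg_sets = _background_sets(
        np.asarray(gc, dtype=float), peak_totals / max(n_cells, 1), n_background, rng
    )
    # background iteration k replaces every peak by its k-th matched peak;
    # mean/sd are computed in two passes to keep exact-zero spreads exact
    def background_deviation(k: int) -> np.ndarray:
        Hk = np.zeros_like(H)
        np.add.at(Hk, bg_sets[:, k], H)
        return deviations(Hk)

    bg_mean = np.zeros_like(raw)
    for k in range(n_background):
        bg_mean += background_deviation(k)
    bg_mean /= n_background
    bg_var = np.zeros_like(raw)
    for k in range(n_background):
        bg_var += (background_deviation(k) - bg_mean) ** 2
    bg_sd = np.sqrt(bg_var / n_background)
    # a background spread at rounding-noise level (degenerate background
    # sets) leaves the z-score undefined rather than amplifying dust
    sd_tol = 1e-10 * (1.0 + np.abs(bg_mean))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(bg_sd > sd_tol, (raw - bg_mean) / bg_sd, np.nan)

    zero_hit = H.sum(axis=0) == 0
    if zero_hit.any():
        warnings.warn(f"{int(zero_hit.sum())} motifs have zero hits; scores undefined", stacklevel=2)
        z[:, zero_hit] = np.nan
        raw[:, zero_hit] = np.nan

    cols = list(motif_hits.columns)
    return DeviationScores(
        z=pd.DataFrame(z, index=cell_names, columns=cols),
        raw=pd.DataFrame(raw, index=cell_names, columns=cols),
        background_sets=bg_sets,
    )


# --- motif-gene pairing -----------------------------------------------------

@dataclass
class MotifGenePair:
    motif: str
    gene: str
    correlation: float
    cluster: str
    motif_score: float
    retained: bool


def cluster_motif_scores(
    deviations: pd.DataFrame, clusters: np.ndarray | pd.Series
) -> pd.DataFrame:
    """Per-cluster motif score: cluster-average deviation minus the minimum
    cluster average across clusters (clusters x motifs, all >= 0)."""
    means = deviations.groupby(np.asarray(clusters)).mean()
    return means - means.min(axis=0)


def motif_gene_pairing(
    deviations: pd.DataFrame,
    expression: pd.DataFrame,
    clusters: np.ndarray | pd.Series,
    motif_families: dict[str, str],
    gene_families: dict[str, str],
    corr_cutoff: float = 0.35,
    percentile_cutoff: float = 90.0,
) -> list[MotifGenePair]:
    """Pair TF motifs with TF genes of the same family.

    Correlations between motif deviation and gene expression are computed
    across cells within each family.  Candidate pairs are the top motif
    (by maximal per-cluster motif score) per gene and the top correlated
    gene per motif; a pair is retained when its correlation exceeds
    ``corr_cutoff`` and its motif score is in the top
    ``100 - percentile_cutoff`` percent for its cluster (boundary ties
    included).  An empty family intersection yields an empty list with a
    warning.
    """
    fams = set(motif_families.values()) & set(gene_families.values())
    if not fams:
        warnings.warn("no family shared between motifs and genes", stacklevel=2)
        return []
    scores = cluster_motif_scores(deviations, clusters)
    best_cluster = scores.idxmax(axis=0)
    best_score = scores.max(axis=0)

    corr: dict[tuple[str, str], float] = {}
    for fam in sorted(fams):
        motifs = [m for m in deviations.columns if motif_families.get(m) == fam]
        genes = [g for g in expression.columns if gene_families.get(g) == fam]
        for m in motifs:
            mv = deviations[m].to_numpy()
            for g in genes:
                gv = expression[g].to_numpy()
                if np.std(mv) == 0 or np.std(gv) == 0:
                    corr[(m, g)] = np.nan
                else:
                    corr[(m, g)] = float(np.corrcoef(mv, gv)[0, 1])

    # top motif score per gene, and top correlated gene per motif
    candidates: set[tuple[str, str]] = set()
    by_gene: dict[str, list[tuple[str, str]]] = {}
    by_motif: dict[str, list[tuple[str, str]]] = {}
    for m, g in corr:
        by_gene.setdefault(g, []).append((m, g))
        by_motif.setdefault(m, []).append((m, g))
    for g, pairs in by_gene.items():
        candidates.add(max(pairs, key=lambda p: best_score[p[0]]))
    for m, pairs in by_motif.items():
        valid = [p for p in pairs if not np.isnan(corr[p])]
        if valid:
            candidates.add(max(valid, key=lambda p: corr[p]))

    # per-cluster top-percentile threshold over that cluster's motif scores
    thresholds = scores.quantile(percentile_cutoff / 100.0, axis=1)

    out = []
    for m, g in sorted(candidates):
        cl = str(best_cluster[m])
        score = float(best_score[m])
        r = corr[(m, g)]
        retained = (
            not np.isnan(r)
            and r > corr_cutoff
            and score >= float(thresholds[best_cluster[m]])
        )
        out.append(
            MotifGenePair(
                motif=m, gene=g, correlation=float(r), cluster=cl,
                motif_score=score, retained=retained,
            )
        )
    return out
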