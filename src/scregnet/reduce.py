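"""Batch-covariate design, residual-dispersion gene selection, regression
scaling, PCA with Marchenko-Pastur retention, and projection of new cells.

The batch-correction design regresses out sequencing depth, cell-cycle
phase and replicate-within-timepoint batch effects from every gene before
variable-gene selection and scaling.  Principal components are retained
while their eigenvalue exceeds the Marchenko-Pastur upper edge
sigma^2 (1 + sqrt(p/n))^2, the largest eigenvalue expected from a
pure-noise covariance of standardized data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class CovariateDesign:
    """n cells x d covariates: total UMI (1), cell-cycle indicators (3),
    and replicate contrasts within each timepoint (sum_t (r_t - 1))."""

    matrix: np.ndarray
    columns: list[str]

    @property
    def n_covariates(self) -> int:
        return self.matrix.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, columns=self.columns)


def build_design(
    obs: pd.DataFrame,
    total_umi_key: str = "total_umi",
    phase_key: str = "cell_cycle_phase",
    timepoint_key: str = "timepoint",
    replicate_key: str = "replicate",
) -> CovariateDesign:
    """Build the batch-correction covariate matrix from cell metadata.

    All three cell-cycle indicator columns (G1, S, G2M) are kept even if a
    phase is absent; downstream regressions handle the implied rank
    deficiency.  For each timepoint with r replicates, r - 1 contrast
    columns are emitted: column j is +1 on replicate j, -1 on replicate
    j + 1, 0 elsewhere (redundant columns are thereby omitted).
    """
    for key in (total_umi_key, timepoint_key, replicate_key):
        if key not in obs:
            raise KeyError(f"metadata field {key!r} required for the design")
    if phase_key not in obs:
        raise KeyError(f"metadata field {phase_key!r} required for the design")

    n = len(obs)
    cols: list[np.ndarray] = [np.asarray(obs[total_umi_key], dtype=float)]
    names = ["total_umi"]
    phases = ("G1", "S", "G2M")
    phase_vals = obs[phase_key].astype(str).to_numpy()
    for p in phases:
        cols.append((phase_vals == p).astype(float))
        names.append(f"phase_{p}")

    tps = list(pd.unique(obs[timepoint_key].astype(str)))
    tp_vals = obs[timepoint_key].astype(str).to_numpy()
    rep_vals = np.asarray(obs[replicate_key])
    for tp in tps:
        in_tp = tp_vals == tp
        reps = sorted(pd.unique(rep_vals[in_tp]))
        for j in range(len(reps) - 1):
            col = np.zeros(n)
            col[in_tp & (rep_vals == reps[j])] = 1.0
            col[in_tp & (rep_vals == reps[j + 1])] = -1.0
            cols.append(col)
            names.append(f"{tp}_rep{reps[j]}_vs_rep{reps[j + 1]}")
    return CovariateDesign(matrix=np.column_stack(cols), columns=names)


def _with_intercept(design: CovariateDesign | np.ndarray | None, n: int) -> np.ndarray:
    ones = np.ones((n, 1))
    if design is None:
        return ones
    M = design.matrix if isinstance(design, CovariateDesign) else np.asarray(design, dtype=float)
    if M.ndim == 1:
        M = M[:, None]
    return np.hstack([ones, M])


def _fit_residuals(Y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Least-squares residuals of every column of Y on X (pinv handles
    rank-deficient designs)."""
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    return Y - X @ beta


@dataclass
class GeneSelection:
    mask: np.ndarray
    means: np.ndarray
    dispersions: np.ndarray
    scaled_dispersions: np.ndarray
    gene_names: list[str] | None = None

    @property
    def selected_genes(self) -> list[str]:
        if self.gene_names is None:
            raise ValueError("no gene names attached")
        return [g for g, keep in zip(self.gene_names, self.mask) if keep]


def select_genes_residual_dispersion(
    normalized_counts: np.ndarray,
    design: CovariateDesign | None,
    mean_cutoff: float = 0.1,
    dispersion_cutoff: float = 0.8,
    n_bins: int = 20,
    gene_names: list[str] | None = None,
) -> GeneSelection:
    """Select variable genes by residual dispersion after batch regression.

    Input is depth-normalized counts (rescaled to a fixed per-cell total,
    no log, no pseudocount).  Per gene, dispersion = log(residual variance /
    mean) where residuals come from least-squares regression on the design
    (with intercept); dispersions are z-scored within ``n_bins`` equal-count
    mean bins; genes pass if mean > mean_cutoff and scaled dispersion >
    dispersion_cutoff.  Zero-residual-variance genes get dispersion -inf.
    """
    Y = np.asarray(normalized_counts, dtype=float)
    n = Y.shape[0]
    X = _with_intercept(design, n)
    resid = _fit_residuals(Y, X)
    means = Y.mean(axis=0)
    res_var = resid.var(axis=0, ddof=1) if n > 1 else np.zeros(Y.shape[1])
    total_var = Y.var(axis=0, ddof=0)
    # residual variance at numerical-noise level counts as exactly zero
    res_var = np.where(res_var <= 1e-12 * np.maximum(total_var, 1e-300), 0.0, res_var)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(
            (res_var > 0) & (means > 0), np.log(res_var / means), -np.inf
        )

    scaled = np.full_like(disp, -np.inf)
    finite = np.isfinite(disp)
    if finite.any():
        bins = pd.qcut(
            pd.Series(means[finite]).rank(method="first"),
            q=min(n_bins, finite.sum()),
            labels=False,
        )
        d = disp[finite]
        z = np.empty_like(d)
        for b in np.unique(bins):
            in_b = bins == b
            sd = d[in_b].std(ddof=1) if in_b.sum() > 1 else 0.0
            z[in_b] = (d[in_b] - d[in_b].mean()) / sd if sd > 0 else 0.0
        scaled[finite] = z

    mask = (means > mean_cutoff) & (scaled > dispersion_cutoff)
    return GeneSelection(
        mask=mask,
        means=means,
        dispersions=disp,
        scaled_dispersions=scaled,
        gene_names=gene_names,
    )


def regress_scale(
    log_normalized: np.ndarray,
    design: CovariateDesign | None,
) -> np.ndarray:
    """Center by regression and scale by residual standard deviation.

    Per gene: subtract the fitted values of a least-squares regression on
    the design (with intercept), then divide by the residual sd.  Genes
    with zero residual variance map to all-zeros.  Rank-deficient designs
    are handled by the pseudoinverse (dependent columns contribute nothing)
    with a warning.
    """
    Y = np.asarray(log_normalized, dtype=float)
    X = _with_intercept(design, Y.shape[0])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        warnings.warn("rank-deficient design; dependent columns dropped", stacklevel=2)
    resid = _fit_residuals(Y, X)
    sd = resid.std(axis=0, ddof=1)
    scale = Y.std(axis=0, ddof=0)
    out = np.zeros_like(resid)
    # genes fit exactly by the design (residual sd at numerical noise) map
    # to all-zeros instead of amplified rounding error
    ok = sd > 1e-10 * np.maximum(scale, 1e-300)
    out[:, ok] = resid[:, ok] / sd[ok]
    return out


@dataclass
class PcaModel:
    """Fitted PCA with Marchenko-Pastur component retention.

    ``loadings`` is genes x retained_components with orthonormal columns;
    ``eigenvalues`` are sample-covariance eigenvalues (non-increasing);
    ``means`` are the training gene means used for centering at projection.
    """

    means: np.ndarray
    loadings: np.ndarray
    eigenvalues: np.ndarray
    retained_components: int
    mp_upper_bound: float
    gene_names: list[str] | None = None

    FORMAT_VERSION = 1

    def save(self, path) -> None:
        """Serialize to a versioned .npz archive."""
        np.savez(
            path,
            format_version=self.FORMAT_VERSION,
            means=self.means,
            loadings=self.loadings,
            eigenvalues=self.eigenvalues,
            retained_components=self.retained_components,
            mp_upper_bound=self.mp_upper_bound,
            gene_names=np.asarray(self.gene_names or [], dtype=object),
        )

    @classmethod
    def load(cls, path) -> "PcaModel":
        with np.load(path, allow_pickle=True) as f:
            if int(f["format_version"]) != cls.FORMAT_VERSION:
                raise ValueError(f"unsupported model format {int(f['format_version'])}")
            genes = [str(g) for g in f["gene_names"]]
            return cls(
                means=f["means"],
                loadings=f["loadings"],
                eigenvalues=f["eigenvalues"],
                retained_components=int(f["retained_components"]),
                mp_upper_bound=float(f["mp_upper_bound"]),
                gene_names=genes or None,
            )


def mp_upper_bound(n: int, p: int, sigma2: float = 1.0) -> float:
    """Marchenko-Pastur upper edge sigma^2 (1 + sqrt(p/n))^2."""
    if n < 2 or p < 2:
        raise ValueError("need at least 2 cells and 2 genes")
    return sigma2 * (1.0 + np.sqrt(p / n)) ** 2


def fit_pca_mp(
    scaled: np.ndarray,
    max_components: int = 100,
    sigma2: float = 1.0,
    use_mp: bool = True,
) -> PcaModel:
    """PCA of a (cells x genes) matrix keeping components above the MP edge.

    Eigenvalues are those of the sample covariance (ddof 1).  With
    ``use_mp``, retained_components = #{eigenvalues > mp_upper_bound},
    capped at ``max_components``; the loading matrix is truncated to the
    retained components.
    """
    X = np.asarray(scaled, dtype=float)
    n, p = X.shape
    bound = mp_upper_bound(n, p, sigma2)
    means = X.mean(axis=0)
    Xc = X - means
    # economy SVD; eigenvalues of the covariance are s^2 / (n - 1)
    _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    eig = s**2 / (n - 1)
    retained = int((eig > bound).sum()) if use_mp else min(max_components, len(eig))
    retained = min(retained, max_components)
    return PcaModel(
        means=means,
        loadings=Vt[:retained].T,
        eigenvalues=eig,
        retained_components=retained,
        mp_upper_bound=bound,
    )


def project_cells(
    query: np.ndarray | pd.DataFrame,
    model: PcaModel,
    gene_names: list[str] | None = None,
    max_missing_fraction: float = 0.5,
) -> np.ndarray:
    """Project query cells into a fitted atlas subspace.

    Queries are centered by the atlas gene means and multiplied by the
    loading matrix, so atlas cells map back to their training scores.
    Genes absent from the query contribute zero after centering; their
    count triggers a warning, and an error above ``max_missing_fraction``.
    """
    if isinstance(query, pd.DataFrame):
        gene_names = list(query.columns)
        query = query.to_numpy(dtype=float)
    Q = np.asarray(query, dtype=float)
    if gene_names is not None and model.gene_names is not None:
        pos = {g: i for i, g in enumerate(gene_names)}
        missing = [g for g in model.gene_names if g not in pos]
        if len(missing) > max_missing_fraction * len(model.gene_names):
            raise ValueError(
                f"{len(missing)} of {len(model.gene_names)} model genes missing"
            )
        if missing:
            warnings.warn(f"{len(missing)} model genes missing; treated as zero", stacklevel=2)
        aligned = np.zeros((Q.shape[0], len(model.gene_names)))
        for j, g in enumerate(model.gene_names):
            if g in pos:
                aligned[:, j] = Q[:, pos[g]] - model.means[j]
        return aligned @ model.loadings
    if Q.shape[1] != model.loadings.shape[0]:
        raise ValueError("query gene dimension does not match the model")
    return (Q - model.means) @ model.loadings
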