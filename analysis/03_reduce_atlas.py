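"""Batch-aware reduction of the filtered synthetic atlas.

Builds the covariate design (UMI depth, cell-cycle indicators, replicate
contrasts), selects genes by residual dispersion, regression-scales the
log-normalized counts, fits PCA with Marchenko-Pastur retention, and
projects a held-out query split back into the fitted subspace.

Writes results/reduce/*.tsv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from scregnet import io, qc, reduce

ROOT = Path(__file__).resolve().parent.parent
OUT = ROOT / "results" / "reduce"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    adata = io.read_scrna_dir(ROOT / "results" / "synthetic" / "scrna")
    adata = adata[~adata.obs.is_contaminant].copy()

    design = reduce.build_design(adata.obs)
    print(f"design: {design.n_covariates} covariates -> {design.columns}")

    X = np.asarray(adata.X.todense(), dtype=float)
    totals = X.sum(axis=1, keepdims=True)
    norm = X / totals * 1e4
    sel = reduce.select_genes_residual_dispersion(
        norm, design, mean_cutoff=0.1, dispersion_cutoff=0.8,
        gene_names=list(adata.var_names),
    )
    print(f"selected {sel.mask.sum()} of {adata.n_vars} genes by residual dispersion")
    pd.DataFrame(
        {"gene": adata.var_names, "mean": sel.means,
         "dispersion": sel.dispersions, "scaled_dispersion": sel.scaled_dispersions,
         "selected": sel.mask}
    ).to_csv(OUT / "gene_selection.tsv", sep="\t", index=False)

    log_norm = np.log2(norm[:, sel.mask] + 1.0)
    scaled = reduce.regress_scale(log_norm, design)
    model = reduce.fit_pca_mp(scaled, max_components=50)
    model.gene_names = sel.selected_genes
    print(f"MP upper bound {model.mp_upper_bound:.3f}; "
          f"retained {model.retained_components} components "
          f"(top eigenvalues {np.round(model.eigenvalues[:5], 2)})")
    pd.DataFrame({"eigenvalue": model.eigenvalues}).to_csv(
        OUT / "eigenvalues.tsv", sep="\t", index=False
    )

    k = max(model.retained_components, 2)
    coords = scaled @ model.loadings[:, :k] if model.retained_components else (
        (scaled - scaled.mean(0)) @ np.linalg.svd(scaled, full_matrices=False)[2][:k].T
    )
    frame = pd.DataFrame(
        coords[:, :k], index=adata.obs_names,
        columns=[f"pc{i + 1}" for i in range(k)],
    )
    frame["true_cluster"] = adata.obs.true_cluster.to_numpy()
    frame.to_csv(OUT / "atlas_coordinates.tsv", sep="\t")

    # round-trip: atlas cells must project onto their training scores
    proj = reduce.project_cells(scaled, model)
    gap = np.abs(proj - (scaled - model.means) @ model.loadings).max() if model.retained_components else 0.0
    print(f"projection round-trip max abs gap: {gap:.2e}")


if __name__ == "__main__":
    main()
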