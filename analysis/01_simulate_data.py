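"""Generate the synthetic multi-omic dataset every later stage consumes.

Emulates the atlas study's statistical structure at desk scale: a
multi-timepoint clustered scRNA count matrix with replicate batch effects,
cell-cycle labels, mitochondrial fractions, planted QC violations and two
contaminant clusters; a clustered scATAC insertion-count matrix with
promoter/distal peak geometry and motif hits; and a sparse linear
ground-truth GRN with expression sampled from its fixed point.

Writes MTX/TSV/BED outputs under results/synthetic/.
"""

from pathlib import Path

import numpy as np

from scregnet import io, simulate

OUT = Path(__file__).resolve().parent.parent / "results" / "synthetic"
SEED = 2026


def main() -> None:
    rna_spec = simulate.ScRnaSimSpec(
        n_cells=3000,
        n_genes=300,
        n_clusters=6,
        mean_expression=10.0,  # per-cell totals ~3000 UMI, as in real data
        seed=SEED,
        planted_contaminants=((60, 0), (40, 1)),
        planted_filter_counts={
            "high_mito": 90, "low_mito": 20, "high_hemoglobin": 5, "low_umi": 30,
        },
    )
    rna = simulate.simulate_scrna(rna_spec)
    io.write_scrna_dir(rna, OUT / "scrna")
    print(f"scRNA: {rna.n_obs} cells x {rna.n_vars} genes, "
          f"{rna.obs.is_contaminant.sum()} contaminant cells, "
          f"median UMI {int(np.median(rna.obs.total_umi))}")

    atac_spec = simulate.ScAtacSimSpec(n_cells=800, n_peaks=400, n_clusters=5, seed=SEED)
    atac_counts, peaks, hits = simulate.simulate_scatac(atac_spec)
    io.write_scrna_dir(atac_counts, OUT / "scatac")
    io.write_bed(peaks, OUT / "peaks.bed")
    io.write_motif_hits(hits, OUT / "motif_hits.tsv")
    print(f"scATAC: {atac_counts.n_obs} cells x {atac_counts.n_vars} peaks "
          f"(max insertion count {atac_counts.X.max()}), "
          f"{int(peaks.is_promoter_planted.sum())} promoter-planted peaks, "
          f"{hits.to_numpy().sum()} motif hits")

    truth = simulate.random_grn(n_genes=30, n_regulators=5, noise_sd=0.5, seed=SEED)
    io.write_edges(truth.edges, OUT / "truth_edges.tsv")
    expr = simulate.simulate_grn_expression(truth, n_cells=2000, seed=SEED + 1)
    np.savetxt(OUT / "grn_expression.tsv", np.asarray(expr.X), delimiter="\t",
               header="\t".join(expr.var_names), comments="")
    print(f"truth GRN: {len(truth.edges)} edges over {len(truth.genes)} genes; "
          f"expression sampled for {expr.n_obs} cells")


if __name__ == "__main__":
    main()
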