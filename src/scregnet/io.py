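"""Plain-text readers/writers for the pipeline's standard formats.

Count matrices go to MatrixMarket (matrix.mtx + barcodes.tsv +
features.tsv) with a cells.tsv metadata table; peaks to BED (0-based
half-open); motif hits and GRN edge lists to TSV.
"""

from __future__ import annotations

from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
from scipy import io as sio
from scipy import sparse


def write_scrna_dir(adata: ad.AnnData, outdir: str | Path) -> Path:
    """Write counts as MTX (features x cells, 10x convention) plus
    barcodes.tsv, features.tsv and cells.tsv metadata."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    X = adata.X if sparse.issparse(adata.X) else sparse.csr_matrix(adata.X)
    sio.mmwrite(outdir / "matrix.mtx", X.T.tocoo())
    pd.Series(adata.obs_names).to_csv(outdir / "barcodes.tsv", index=False, header=False)
    pd.Series(adata.var_names).to_csv(outdir / "features.tsv", index=False, header=False)
    adata.obs.to_csv(outdir / "cells.tsv", sep="\t")
    return outdir


def read_scrna_dir(indir: str | Path) -> ad.AnnData:
    indir = Path(indir)
    X = sparse.csr_matrix(sio.mmread(indir / "matrix.mtx").T)
    barcodes = pd.read_csv(indir / "barcodes.tsv", header=None)[0].tolist()
    features = pd.read_csv(indir / "features.tsv", header=None)[0].tolist()
    obs = pd.read_csv(indir / "cells.tsv", sep="\t", index_col=0)
    obs = obs.loc[barcodes]
    return ad.AnnData(X=X, obs=obs, var=pd.DataFrame(index=features))


def write_bed(peaks: pd.DataFrame, path: str | Path) -> Path:
    """BED: chrom, start, end, name[, score]; 0-based half-open."""
    path = Path(path)
    cols = [c for c in ("chrom", "start", "end", "name", "score") if c in peaks]
    peaks[cols].to_csv(path, sep="\t", index=False, header=False)
    return path


def read_bed(path: str | Path, names=("chrom", "start", "end", "name")) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None)
    df.columns = list(names)[: df.shape[1]]
    return df


def write_motif_hits(hits: pd.DataFrame, path: str | Path) -> Path:
    """Long format (peak_id, motif_id), one row per hit."""
    long = (
        hits.stack().rename("hit").reset_index()
        .rename(columns={"level_0": "peak_id", "level_1": "motif_id", "name": "peak_id"})
    )
    long = long[long["hit"]]
    long[["peak_id", "motif_id"]].to_csv(path, sep="\t", index=False)
    return Path(path)


def read_motif_hits(path: str | Path, peaks: list[str], motifs: list[str] | None = None) -> pd.DataFrame:
    long = pd.read_csv(path, sep="\t")
    if motifs is None:
        motifs = sorted(long["motif_id"].unique())
    hits = pd.DataFrame(False, index=pd.Index(peaks, name="peak_id"), columns=motifs)
    for pk, m in long[["peak_id", "motif_id"]].itertuples(index=False):
        hits.at[pk, m] = True
    return hits


def write_edges(edges: pd.DataFrame, path: str | Path) -> Path:
    edges.to_csv(path, sep="\t", index=False)
    return Path(path)
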