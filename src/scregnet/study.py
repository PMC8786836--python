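"""Reported cell-accounting tables of the pharyngeal endoderm atlas study.

These constants are the published QC bookkeeping of the mouse pharyngeal
endoderm datasets (scRNA atlas E9.5-E12.5, Foxn1-knockout scRNA experiment,
scATAC atlas E11.5-E12.5): starting cell numbers, per-rule removal counts
and per-sample breakdowns.  They are inputs to the ledger-replay functions,
which recompute every downstream total from them.
"""

from __future__ import annotations

from scregnet.qc import LedgerReport, doublet_quota

# --- scRNA atlas -----------------------------------------------------------

ATLAS_STARTING_CELLS = 57_850

# contaminant clusters removed after initial Louvain clustering, with the
# signature that motivated each removal
ATLAS_CLUSTER_REMOVALS = [
    ("cluster_33_neuronal", 459),
    ("cluster_41_neural_crest", 79),
    ("cluster_36_endothelial", 381),
    ("cluster_38_neural_crest", 247),
    ("cluster_39_otic_vesicle", 231),
]

ATLAS_CELL_FILTER_REMOVALS = [
    ("mito_fraction_over_7pct", 2122),
    ("mito_fraction_under_1pct", 270),
    ("hbb_bt_log_norm_over_1", 17),
]

ATLAS_CELLS_PER_SAMPLE = {
    "E9.5_rep1": 5734,
    "E9.5_rep2": 7611,
    "E10.5_rep1": 4743,
    "E10.5_rep2": 4129,
    "E10.5_rep3": 4248,
    "E11.5_rep1": 5385,
    "E11.5_rep2": 3141,
    "E11.5_rep3": 7967,
    "E12.5_rep1": 4885,
    "E12.5_rep2": 6201,
}

# replicate structure of the atlas: (timepoint, n_replicates)
ATLAS_REPLICATES = (("E9.5", 2), ("E10.5", 3), ("E11.5", 3), ("E12.5", 2))

# --- Foxn1 knockout scRNA experiment --------------------------------------

KO_STARTING_CELLS = 29_276

KO_CLUSTER_REMOVALS = [
    ("cluster_0_low_depth", 3362),
    ("cluster_10_low_depth", 1150),
    ("cluster_24_low_depth", 318),
    ("cluster_27_contaminant", 207),
    ("cluster_28_contaminant", 132),
    ("cluster_30_contaminant", 37),
]

KO_CELL_FILTER_REMOVALS = [
    ("under_2000_umi", 2121),
    ("classified_contaminant", 45),
]

KO_CELLS_PER_SAMPLE = {
    "E12.5het_rep1": 6805,
    "E12.5het_rep2": 2258,
    "E12.5homo_rep1": 8070,
    "E12.5homo_rep2": 4771,
}

# --- scATAC atlas ----------------------------------------------------------

# cells per sample surviving the depth (>= 3000 unique fragments) and TSS
# enrichment (>= 4) filters; the doublet quota is computed from these
ATAC_CELLS_AFTER_DEPTH_TSS = {
    "E11.5_rep1": 4320,
    "E11.5_rep2": 1273,
    "E12.5_rep1": 3576,
    "E12.5_rep2": 4784,
}

ATAC_CELLS_PER_SAMPLE_FINAL = {
    "E11.5_rep1": 3248,
    "E11.5_rep2": 1075,
    "E12.5_rep1": 2813,
    "E12.5_rep2": 3754,
}


def atlas_ledger() -> LedgerReport:
    """Replay the scRNA atlas exclusions from 57,850 cells."""
    return LedgerReport.from_removals(
        ATLAS_STARTING_CELLS,
        ATLAS_CLUSTER_REMOVALS + ATLAS_CELL_FILTER_REMOVALS,
        per_sample=ATLAS_CELLS_PER_SAMPLE,
    )


def ko_ledger() -> LedgerReport:
    """Replay the knockout-experiment exclusions from 29,276 cells."""
    return LedgerReport.from_removals(
        KO_STARTING_CELLS,
        KO_CLUSTER_REMOVALS + KO_CELL_FILTER_REMOVALS,
        per_sample=KO_CELLS_PER_SAMPLE,
    )


def atac_doublet_ledger(divisor: int = 100_000) -> LedgerReport:
    """Apply the per-sample doublet quota to the post-depth-filter counts.

    The removal per sample is computed as floor(n^2 / divisor), not read
    from a table.
    """
    start = sum(ATAC_CELLS_AFTER_DEPTH_TSS.values())
    removals = [
        (f"doublet_quota_{sample}", doublet_quota(n, divisor))
        for sample, n in ATAC_CELLS_AFTER_DEPTH_TSS.items()
    ]
    return LedgerReport.from_removals(start, removals)


def timepoint_totals(per_sample: dict[str, int]) -> dict[str, int]:
    """Sum a per-sample breakdown to per-timepoint totals."""
    out: dict[str, int] = {}
    for sample, n in per_sample.items():
        tp = sample.split("_")[0]
        out[tp] = out.get(tp, 0) + n
    return out
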