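"""Ordered cell-filtering rules with auditable ledger accounting.

Quality control in the atlas pipeline is a sequence of exclusions —
cluster-level removals of contaminant populations, then cell-level
thresholds on mitochondrial fraction, hemoglobin expression or UMI depth,
plus a per-sample doublet quota for the chromatin data.  Each run produces
a :class:`LedgerReport` whose telescoping arithmetic (remaining_i =
remaining_{i-1} - removed_i) makes the printed cell counts auditable.

Rule wording is strict: "over 7%" removes fractions strictly above 0.07,
"under 1%" strictly below 0.01, "at least" is inclusive.  A cell failing
several rules is removed once and attributed to the first rule it fails in
the declared order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd

DIRECTIONS = {
    "greater_than": lambda v, t: v > t,
    "less_than": lambda v, t: v < t,
    "at_least": lambda v, t: v >= t,
    "at_most": lambda v, t: v <= t,
}


@dataclass(frozen=True)
class FilterRule:
    """A cell-level threshold rule: remove cells whose ``field`` compares
    ``direction`` (strict for greater/less_than) against ``threshold``."""

    name: str
    field: str
    direction: str
    threshold: float

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS:
            raise ValueError(f"unknown direction {self.direction!r}")
        if not np.isfinite(self.threshold):
            raise ValueError("threshold must be finite")

    def violates(self, values: np.ndarray) -> np.ndarray:
        return DIRECTIONS[self.direction](np.asarray(values, dtype=float), self.threshold)


@dataclass
class LedgerReport:
    """Ordered record of filter rules applied and cells removed/remaining."""

    starting_count: int
    entries: list[tuple[str, int, int]] = field(default_factory=list)
    per_sample: dict[str, int] = field(default_factory=dict)

    @property
    def final_count(self) -> int:
        return self.entries[-1][2] if self.entries else self.starting_count

    def add(self, name: str, removed: int) -> None:
        self.entries.append((name, int(removed), self.final_count - int(removed)))
        self.validate()

    def validate(self) -> None:
        remaining = self.starting_count
        for name, removed, after in self.entries:
            if removed < 0 or after != remaining - removed:
                raise ValueError(f"ledger does not telescope at rule {name!r}")
            remaining = after
        if self.per_sample and sum(self.per_sample.values()) != self.final_count:
            raise ValueError("per-sample breakdown does not sum to final count")

    @classmethod
    def from_removals(
        cls,
        starting_count: int,
        removals: list[tuple[str, int]],
        per_sample: dict[str, int] | None = None,
    ) -> "LedgerReport":
        """Replay a printed ledger given per-rule removal counts."""
        report = cls(starting_count=starting_count)
        for name, removed in removals:
            report.add(name, removed)
        if per_sample is not None:
            report.per_sample = dict(per_sample)
            report.validate()
        return report

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.entries, columns=["rule", "cells_removed", "cells_remaining"]
        )

    def to_json_dict(self) -> dict:
        return {
            "starting_count": self.starting_count,
            "entries": [
                {"rule": n, "cells_removed": r, "cells_remaining": a}
                for n, r, a in self.entries
            ],
            "final_count": self.final_count,
            "per_sample": dict(self.per_sample),
        }


def _per_sample_counts(adata: ad.AnnData, sample_key: str | None) -> dict[str, int]:
    if sample_key is None or sample_key not in adata.obs:
        return {}
    return adata.obs[sample_key].value_counts().to_dict()


def apply_cell_filters(
    adata: ad.AnnData,
    rules: list[FilterRule],
    sample_key: str | None = "sample",
) -> tuple[ad.AnnData, LedgerReport]:
    """Apply cell-level rules in order; attribute each removed cell to the
    first rule it fails.  Raises ``KeyError`` naming any missing obs field."""
    for rule in rules:
        if rule.field not in adata.obs:
            raise KeyError(f"metadata field {rule.field!r} required by rule {rule.name!r}")
    report = LedgerReport(starting_count=adata.n_obs)
    alive = np.ones(adata.n_obs, dtype=bool)
    for rule in rules:
        bad = rule.violates(adata.obs[rule.field].to_numpy()) & alive
        report.add(rule.name, int(bad.sum()))
        alive &= ~bad
    filtered = adata[alive].copy()
    report.per_sample = _per_sample_counts(filtered, sample_key)
    report.validate()
    return filtered, report


def apply_cluster_exclusions(
    adata: ad.AnnData,
    cluster_labels,
    excluded: list,
    sample_key: str | None = "sample",
) -> tuple[ad.AnnData, LedgerReport]:
    """Remove all cells of the excluded clusters, one ledger entry per cluster."""
    labels = (
        adata.obs[cluster_labels].to_numpy()
        if isinstance(cluster_labels, str)
        else np.asarray(cluster_labels)
    )
    if len(labels) != adata.n_obs:
        raise ValueError("cluster labels must cover all cells")
    known = set(pd.unique(labels))
    unknown = [c for c in excluded if c not in known]
    if unknown:
        raise ValueError(f"unknown cluster ids: {unknown}")
    report = LedgerReport(starting_count=adata.n_obs)
    alive = np.ones(adata.n_obs, dtype=bool)
    for cl in excluded:
        bad = (labels == cl) & alive
        report.add(f"cluster_{cl}", int(bad.sum()))
        alive &= ~bad
    filtered = adata[alive].copy()
    report.per_sample = _per_sample_counts(filtered, sample_key)
    report.validate()
    return filtered, report


def doublet_quota(n_cells: int, divisor: int = 100_000) -> int:
    """Per-sample doublet removal quota floor(n_cells^2 / divisor).

    The divisor defaults to 100,000, the value consistent with the atlas
    study's per-sample removals (e.g. 186 of 4320 cells).
    """
    if n_cells < 0:
        raise ValueError("n_cells must be non-negative")
    if divisor <= 0:
        raise ValueError("divisor must be positive")
    return (n_cells * n_cells) // divisor


def log_normalized_expression(
    adata: ad.AnnData,
    gene: str,
    scale: float = 1e4,
    base: float = 2.0,
) -> np.ndarray:
    """Per-cell log-normalized expression of one gene: counts rescaled to
    ``scale`` per cell, then log(1 + x) in the given base (base 2 for the
    atlas preset, natural log with ``base=np.e`` for the knockout preset)."""
    if gene not in adata.var_names:
        raise KeyError(f"gene {gene!r} absent from matrix")
    col = adata[:, gene].X
    col = np.asarray(col.todense()).ravel() if hasattr(col, "todense") else np.asarray(col).ravel()
    totals = np.asarray(adata.X.sum(axis=1)).ravel()
    with np.errstate(divide="ignore", invalid="ignore"):
        norm = np.where(totals > 0, col * scale / totals, 0.0)
    return np.log1p(norm) / np.log(base)
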