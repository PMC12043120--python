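"""Pooled CRISPR-screen enrichment: CPM normalization, guide log10 fold-change,
gene-level score and rank.

A guide enriched in the selected (T-cell pressure) arm relative to the
control arm indicates that losing the targeted gene confers resistance to
killing; the gene score is the mean (optionally median) of its guides'
log10 fold-changes, and genes are ranked by descending score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ScreenCountTable

__all__ = ["ScreenResult", "normalize_cpm", "guide_log10_fc", "gene_rank", "DEFAULT_CPM_PSEUDOCOUNT"]

#: pseudocount (in CPM units) added before taking log10 fold-changes
DEFAULT_CPM_PSEUDOCOUNT = 0.5


@dataclass
class ScreenResult:
    """Guide-level table (cpm per condition, log10_fc) and gene-level table
    (gene_score, n_guides, rank; optional second-control score)."""

    guide_table: pd.DataFrame
    gene_table: pd.DataFrame

    def rank_of(self, gene: str) -> int:
        row = self.gene_table[self.gene_table["gene"] == gene]
        if row.empty:
            raise KeyError(f"gene {gene!r} not in the screen result")
        return int(row["rank"].iloc[0])


def normalize_cpm(counts: ScreenCountTable) -> pd.DataFrame:
    """Counts-per-million per condition: 1e6 * count / condition total."""
    totals = counts.counts.sum(axis=0)
    zero = totals[totals == 0].index.tolist()
    if zero:
        raise ValueError(f"conditions with zero total counts: {zero}")
    return 1e6 * counts.counts / totals


def guide_log10_fc(cpm_selected, cpm_control, pseudocount: float = DEFAULT_CPM_PSEUDOCOUNT):
    """log10((cpm_selected + c) / (cpm_control + c)) per guide."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    return np.log10((np.asarray(cpm_selected, dtype=float) + pseudocount)
                    / (np.asarray(cpm_control, dtype=float) + pseudocount))


def gene_rank(
    counts: ScreenCountTable,
    control: str = "control",
    selected: str = "selected",
    control2: str | None = None,
    pseudocount: float = DEFAULT_CPM_PSEUDOCOUNT,
    agg: str = "mean",
) -> ScreenResult:
    """Full screen ranking: CPM -> guide log10 FC -> gene score -> rank.

    ``control2`` (e.g. an irrelevant-T-cell arm) adds a side-by-side
    ``gene_score2`` computed against that arm; the rank always follows the
    primary contrast. Ties in gene_score break lexicographically by gene id.
    """
    for cond in filter(None, (control, selected, control2)):
        if cond not in counts.conditions:
            raise KeyError(f"condition {cond!r} not in the count table")
    if agg not in ("mean", "median"):
        raise ValueError(f"unknown aggregation {agg!r}")
    cpm = normalize_cpm(counts)
    lfc = guide_log10_fc(cpm[selected], cpm[control], pseudocount)
    guide_table = cpm.copy()
    guide_table.columns = [f"cpm_{c}" for c in guide_table.columns]
    guide_table["log10_fc"] = lfc
    guide_table["gene"] = counts.gene_of.to_numpy()
    if control2 is not None:
        guide_table["log10_fc2"] = guide_log10_fc(cpm[selected], cpm[control2], pseudocount)

    agg_fn = "mean" if agg == "mean" else "median"
    grouped = guide_table.groupby("gene")
    gene_table = grouped["log10_fc"].agg(gene_score=agg_fn).reset_index()
    gene_table["n_guides"] = grouped.size().reindex(gene_table["gene"]).to_numpy()
    if control2 is not None:
        gene_table["gene_score2"] = (
            grouped["log10_fc2"].agg(agg_fn).reindex(gene_table["gene"]).to_numpy()
        )
    gene_table = gene_table.sort_values(
        ["gene_score", "gene"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    gene_table["rank"] = np.arange(1, len(gene_table) + 1)
    return ScreenResult(guide_table.reset_index(), gene_table)
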