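"""End-to-end drivers: the pan-cancer correlation study and the screen re-analysis.

Each run reads validated inputs, executes the stage chain, and writes result
tables plus a JSON manifest (inputs, parameters, per-stage row counts).
Outputs are byte-reproducible from config + seed: nothing time- or
path-order-dependent is written.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

from . import __version__
from .correlate import (
    aggregate_median_rank,
    cohort_correlations,
    count_significant_cohorts,
)
from .io import FLOAT_FMT, read_expression_matrix, read_screen_counts
from .scores import cyt_score, single_gene_proxy
from .screen import gene_rank

logger = logging.getLogger(__name__)

__all__ = ["PancancerConfig", "ScreenConfig", "run_pancancer", "run_screen"]


@dataclass
class PancancerConfig:
    matrix_path: str
    metadata_path: str
    out_dir: str
    proxy: str = "CD8A"  # a gene id, or "cyt" for the cytolytic score
    scale: str = "log2p1"
    alpha: float = 0.05
    min_samples: int = 10
    min_cohorts: int = 1
    cyt_genes: tuple[str, str] = ("GZMB", "PRF1")
    cyt_pseudocount: float = 0.01

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.min_samples < 3:
            raise ValueError("min_samples must be >= 3")
        for p in (self.matrix_path, self.metadata_path):
            if not Path(p).exists():
                raise FileNotFoundError(p)


@dataclass
class ScreenConfig:
    counts_path: str
    mapping_path: str
    out_dir: str
    control: str = "control"
    selected: str = "selected"
    control2: str | None = None
    pseudocount: float = 0.5
    agg: str = "mean"

    def __post_init__(self) -> None:
        for p in (self.counts_path, self.mapping_path):
            if not Path(p).exists():
                raise FileNotFoundError(p)


def _write_manifest(out_dir: Path, config, stage_rows: dict[str, int]) -> None:
    manifest = {
        "tool": "immunoscape",
        "version": __version__,
        "parameters": dataclasses.asdict(config),
        "stage_rows": stage_rows,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def run_pancancer(config: PancancerConfig) -> Path:
    """score -> correlate -> aggregate -> count significant; returns the result dir.

    Writes per_cohort_correlations.tsv (gene, cohort, r, p, n, flag),
    gene_rank.tsv (gene, median_r, n_cohorts, rank, percentile),
    significant_cohorts.tsv (gene, n_significant) and manifest.json.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    matrix = read_expression_matrix(config.matrix_path, config.metadata_path)
    logger.info("matrix: %d genes x %d samples, %d cohorts",
                len(matrix.gene_ids), matrix.n_samples(), len(matrix.cohorts))

    if config.proxy.lower() == "cyt":
        proxy = cyt_score(matrix, *config.cyt_genes, pseudocount=config.cyt_pseudocount)
    else:
        proxy = single_gene_proxy(matrix, config.proxy, scale=config.scale)

    corr = cohort_correlations(matrix, proxy, min_samples=config.min_samples, scale=config.scale)
    rank = aggregate_median_rank(corr, min_cohorts=config.min_cohorts)
    sig = count_significant_cohorts(corr, alpha=config.alpha, direction="positive")

    corr.table.to_csv(out_dir / "per_cohort_correlations.tsv", sep="\t", index=False,
                      float_format=FLOAT_FMT)
    rank.table.to_csv(out_dir / "gene_rank.tsv", sep="\t", index=False, float_format=FLOAT_FMT)
    sig.rename("n_significant").to_frame().to_csv(
        out_dir / "significant_cohorts.tsv", sep="\t", index_label="gene")
    skipped = int((corr.table["flag"] != "ok").sum())
    _write_manifest(out_dir, config, {
        "genes": len(matrix.gene_ids),
        "samples": matrix.n_samples(),
        "cohorts": len(matrix.cohorts),
        "correlation_entries": len(corr.table),
        "skipped_entries": skipped,
        "ranked_genes": len(rank.table),
    })
    return out_dir


def run_screen(config: ScreenConfig) -> Path:
    """normalize -> guide log10 FC -> gene rank; returns the result dir."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    counts = read_screen_counts(config.counts_path, config.mapping_path)
    logger.info("screen: %d guides, conditions %s", len(counts.guide_ids), counts.conditions)
    result = gene_rank(
        counts,
        control=config.control,
        selected=config.selected,
        control2=config.control2,
        pseudocount=config.pseudocount,
        agg=config.agg,
    )
    result.guide_table.to_csv(out_dir / "guide_table.tsv", sep="\t", index=False,
                              float_format=FLOAT_FMT)
    result.gene_table.to_csv(out_dir / "gene_table.tsv", sep="\t", index=False,
                             float_format=FLOAT_FMT)
    _write_manifest(out_dir, config, {
        "guides": len(result.guide_table),
        "genes": len(result.gene_table),
    })
    return out_dir
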