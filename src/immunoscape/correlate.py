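"""Per-cohort gene-vs-infiltration Pearson correlation and pan-cancer ranking.

The core procedure: within each cohort, correlate every gene's expression
with an infiltration proxy (Pearson r with a two-sided t-test p-value), then
aggregate each gene's per-cohort coefficients by their median and rank genes
genome-wide by that median. Percentiles are computed within the ranked
universe, so "top 5%" means the top 5% of genes the input matrix provides.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix
from .scores import InfiltrationVector

logger = logging.getLogger(__name__)

__all__ = [
    "CohortCorrelationResult",
    "GeneRankTable",
    "pearson_with_p",
    "cohort_correlations",
    "aggregate_median_rank",
    "count_significant_cohorts",
    "bh_adjust",
]

#: flag values in the per-(gene, cohort) table
FLAG_OK = "ok"
FLAG_LOW_N = "low_n"
FLAG_ZERO_VARIANCE = "zero_variance"


@dataclass
class CohortCorrelationResult:
    """Tidy per-(gene, cohort) table: gene, cohort, r, p, n, flag."""

    table: pd.DataFrame

    def ok(self) -> pd.DataFrame:
        return self.table[self.table["flag"] == FLAG_OK]


@dataclass
class GeneRankTable:
    """Per-gene table: median_r, n_cohorts, rank (1 = largest median_r), percentile."""

    table: pd.DataFrame

    def percentile_of(self, gene: str) -> float:
        row = self.table[self.table["gene"] == gene]
        if row.empty:
            raise KeyError(f"gene {gene!r} not ranked")
        return float(row["percentile"].iloc[0])


def pearson_with_p(x, y) -> tuple[float, float, int]:
    """Sample Pearson r with the two-sided t-test p-value on n-2 df.

    |r| = 1 returns p = 0 by convention. Zero-variance input raises; the
    pipeline-level sweep flags those entries instead of raising.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt((xc * xc).sum())
    sy = np.sqrt((yc * yc).sum())
    if sx == 0 or sy == 0:
        raise ValueError("zero-variance input")
    r = float((xc * yc).sum() / (sx * sy))
    r = max(-1.0, min(1.0, r))
    if abs(r) >= 1.0 - 1e-12:  # collinear up to rounding
        r = math.copysign(1.0, r)
        return r, 0.0, n
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return r, p, n


def _pearson_matrix(block: np.ndarray, proxy: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised Pearson r of every row of ``block`` against ``proxy``.

    Returns (r, p, zero_variance mask); r/p are NaN where a row is constant.
    """
    n = proxy.size
    bc = block - block.mean(axis=1, keepdims=True)
    pc = proxy - proxy.mean()
    sb = np.sqrt((bc * bc).sum(axis=1))
    sp = np.sqrt((pc * pc).sum())
    zero_var = sb == 0
    denom = np.where(zero_var, np.nan, sb * sp)
    r = (bc @ pc) / denom
    r = np.clip(r, -1.0, 1.0)
    collinear = np.abs(r) >= 1.0 - 1e-12
    r = np.where(collinear, np.sign(r), r)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(collinear, 0.0, p)
    return r, p, zero_var


def cohort_correlations(
    matrix: ExpressionMatrix,
    proxy: InfiltrationVector,
    min_samples: int = 10,
    scale: str = "log2p1",
) -> CohortCorrelationResult:
    """Correlate every gene with the proxy, independently per cohort.

    Expression is put on ``scale`` (log2(TPM+1) by default, or raw TPM) before
    correlating. When the proxy is a single gene present in the matrix, that
    gene is excluded from the result. Cohorts below ``min_samples`` and
    zero-variance genes are flagged, not dropped silently.
    """
    if min_samples < 3:
        raise ValueError("min_samples must be >= 3")
    if scale not in ("log2p1", "tpm"):
        raise ValueError(f"unknown scale {scale!r}")
    missing = [s for s in matrix.sample_ids if s not in proxy.values.index]
    if missing:
        raise ValueError(f"proxy does not cover samples: {missing[:5]}")

    genes = [g for g in matrix.gene_ids if g != proxy.proxy_name]
    rows: list[pd.DataFrame] = []
    for cohort in matrix.cohorts:
        sub = matrix.subset_cohort(cohort)
        n = sub.n_samples()
        if n < min_samples:
            logger.info("cohort %s skipped: n=%d < min_samples=%d", cohort, n, min_samples)
            rows.append(
                pd.DataFrame(
                    {"gene": genes, "cohort": cohort, "r": np.nan, "p": np.nan, "n": n, "flag": FLAG_LOW_N}
                )
            )
            continue
        block = sub.values.loc[genes].to_numpy(dtype=float)
        if scale == "log2p1":
            block = np.log2(block + 1.0)
        pvec = proxy.values.loc[sub.sample_ids].to_numpy(dtype=float)
        r, p, zero_var = _pearson_matrix(block, pvec)
        flag = np.where(zero_var, FLAG_ZERO_VARIANCE, FLAG_OK)
        rows.append(pd.DataFrame({"gene": genes, "cohort": cohort, "r": r, "p": p, "n": n, "flag": flag}))
        n_zv = int(zero_var.sum())
        if n_zv:
            logger.info("cohort %s: %d zero-variance genes flagged", cohort, n_zv)
    table = pd.concat(rows, ignore_index=True)
    return CohortCorrelationResult(table)


def aggregate_median_rank(result: CohortCorrelationResult, min_cohorts: int = 1) -> GeneRankTable:
    """Median per-cohort r per gene, ranked descending (1 = most positive).

    Genes with fewer than ``min_cohorts`` computed entries are excluded and
    logged. Ties in median_r break lexicographically by gene id, so output is
    byte-stable. percentile = 100 * (rank - 1) / (G - 1).
    """
    ok = result.ok()
    agg = ok.groupby("gene")["r"].agg(median_r="median", n_cohorts="size").reset_index()
    dropped = agg[agg["n_cohorts"] < min_cohorts]
    if not dropped.empty:
        logger.info("excluded %d genes below min_cohorts=%d", len(dropped), min_cohorts)
    agg = agg[agg["n_cohorts"] >= min_cohorts]
    agg = agg.sort_values(["median_r", "gene"], ascending=[False, True], kind="mergesort")
    agg = agg.reset_index(drop=True)
    g = len(agg)
    agg["rank"] = np.arange(1, g + 1)
    agg["percentile"] = 100.0 * (agg["rank"] - 1) / max(g - 1, 1)
    return GeneRankTable(agg)


def count_significant_cohorts(
    result: CohortCorrelationResult, alpha: float = 0.05, direction: str = "positive"
) -> pd.Series:
    """Per-gene count of cohorts with p < alpha and r in the requested direction."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    ok = result.ok()
    sig = ok["p"] < alpha
    if direction == "positive":
        sig &= ok["r"] > 0
    elif direction == "negative":
        sig &= ok["r"] < 0
    elif direction != "either":
        raise ValueError(f"unknown direction {direction!r}")
    counts = ok.loc[sig].groupby("gene").size()
    return counts.reindex(ok["gene"].unique(), fill_value=0).astype(int)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order, clipped at 1."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]
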