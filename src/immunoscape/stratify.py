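"""Tercile stratification, two-group differential expression, and enrichment.

The stratified analysis mirrors a common bulk-cohort design: order the
samples of one cohort by a gene of interest, take the bottom and top terciles
as "low" and "high" groups, test every gene for a shift between the groups
(median-ratio log2 fold-change + Mann-Whitney U), and summarise the high
tercile's signature by hypergeometric over-representation against gene sets.
The induction-attenuation contrast compares two such fold-change profiles
(e.g. IFN-gamma response in control vs knockout cells) gene by gene.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import comb

from .correlate import bh_adjust
from .io import ExpressionMatrix, GeneSetCollection

__all__ = [
    "DEResult",
    "tercile_stratify",
    "differential_expression",
    "rank_plot_data",
    "enrichment_hypergeometric",
    "induction_attenuation",
    "mann_whitney_p",
]

#: group sizes up to which the Mann-Whitney p is computed by exact enumeration
EXACT_MAX = 8


@dataclass
class DEResult:
    """Per-gene DE table: gene, median_A, median_B, log2_fc, p, q."""

    table: pd.DataFrame

    def lfc_of(self, gene: str) -> float:
        row = self.table[self.table["gene"] == gene]
        if row.empty:
            raise KeyError(f"gene {gene!r} not tested")
        return float(row["log2_fc"].iloc[0])


def tercile_stratify(values: pd.Series) -> pd.Series:
    """Label samples {low, mid, high} by tercile of ``values``.

    The first floor(n/3) samples after a stable ascending sort on
    (value, sample_id) are "low", the last floor(n/3) are "high"; ties at a
    boundary therefore resolve deterministically by sample id.
    """
    n = len(values)
    if n < 3:
        raise ValueError("need at least 3 samples to stratify")
    order = sorted(values.index, key=lambda s: (values[s], s))
    k = n // 3
    labels = pd.Series("mid", index=values.index, name="tercile")
    labels[order[:k]] = "low"
    labels[order[n - k:]] = "high"
    return labels


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Mann-Whitney U of a over b: #{a > b} + 0.5 * #{a == b} over all pairs."""
    diff = a[:, None] - b[None, :]
    return float((diff > 0).sum() + 0.5 * (diff == 0).sum())


def mann_whitney_p(a, b, alternative: str = "two-sided") -> float:
    """Two-group Mann-Whitney U p-value.

    Exact enumeration of all group assignments when both groups have at most
    ``EXACT_MAX`` observations, or whenever the enumeration is small anyway
    (valid with ties); otherwise the tie-corrected normal approximation. An
    all-tied comparison returns p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = a.size, b.size
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0
    u = _u_statistic(a, b)
    m = n1 * n2

    small_enumeration = comb(n1 + n2, n1, exact=True) <= comb(2 * EXACT_MAX, EXACT_MAX, exact=True)
    if (n1 <= EXACT_MAX and n2 <= EXACT_MAX) or small_enumeration:
        us = np.array(
            [
                _u_statistic(pooled[list(idx)], np.delete(pooled, list(idx)))
                for idx in combinations(range(n1 + n2), n1)
            ]
        )
        if alternative == "greater":
            return float((us >= u - 1e-12).mean())
        if alternative == "less":
            return float((us <= u + 1e-12).mean())
        dev = np.abs(us - m / 2.0)
        return float((dev >= abs(u - m / 2.0) - 1e-12).mean())

    # tie-corrected normal approximation (no continuity correction)
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
    var = m / 12.0 * ((n + 1) - tie_term)
    z = (u - m / 2.0) / np.sqrt(var)
    if alternative == "greater":
        return float(stats.norm.sf(z))
    if alternative == "less":
        return float(stats.norm.cdf(z))
    return float(2.0 * stats.norm.sf(abs(z)))


def differential_expression(
    matrix: ExpressionMatrix,
    group_a: list[str],
    group_b: list[str],
    pseudocount: float = 1.0,
) -> DEResult:
    """Median-ratio log2 fold-change (A vs B) with Mann-Whitney p and BH q.

    log2_fc = log2((median_A + pseudocount) / (median_B + pseudocount)) on the
    TPM scale; p-values come from :func:`mann_whitney_p`, adjusted across all
    tested genes.
    """
    set_a, set_b = set(group_a), set(group_b)
    if not set_a or not set_b:
        raise ValueError("both groups must be non-empty")
    if set_a & set_b:
        raise ValueError(f"groups overlap: {sorted(set_a & set_b)[:5]}")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    a_block = matrix.values[list(group_a)].to_numpy(dtype=float)
    b_block = matrix.values[list(group_b)].to_numpy(dtype=float)
    med_a = np.median(a_block, axis=1)
    med_b = np.median(b_block, axis=1)
    lfc = np.log2((med_a + pseudocount) / (med_b + pseudocount))
    pvals = np.array(
        [mann_whitney_p(a_block[i], b_block[i]) for i in range(matrix.values.shape[0])]
    )
    q = bh_adjust(np.clip(pvals, np.nextafter(0, 1), 1.0))
    table = pd.DataFrame(
        {
            "gene": matrix.gene_ids,
            "median_A": med_a,
            "median_B": med_b,
            "log2_fc": lfc,
            "p": pvals,
            "q": q,
        }
    )
    return DEResult(table)


def rank_plot_data(
    de: DEResult, highlight: set[str], alternative: str = "two-sided"
) -> tuple[pd.DataFrame, float]:
    """Genes ordered by descending log2_fc with an in-set flag, plus a
    rank-enrichment p comparing in-set vs out-of-set fold-changes
    (Mann-Whitney U). With no out-group the p is 1 by convention."""
    tested = set(de.table["gene"])
    inter = highlight & tested
    if not inter:
        raise ValueError("highlight set does not intersect the tested genes")
    tab = de.table.sort_values(["log2_fc", "gene"], ascending=[False, True], kind="mergesort")
    tab = tab.reset_index(drop=True)
    tab["in_set"] = tab["gene"].isin(inter)
    in_vals = tab.loc[tab["in_set"], "log2_fc"].to_numpy()
    out_vals = tab.loc[~tab["in_set"], "log2_fc"].to_numpy()
    if out_vals.size == 0:
        p = 1.0
    else:
        p = mann_whitney_p(in_vals, out_vals, alternative=alternative)
    return tab[["gene", "log2_fc", "in_set"]], p


def enrichment_hypergeometric(
    selected: set[str], sets: GeneSetCollection, universe: set[str]
) -> pd.DataFrame:
    """Over-representation of ``selected`` genes in each gene set.

    Upper-tail hypergeometric p = P(X >= k) with N = |universe|,
    K = |set & universe|, n = |selected|, k = |set & selected|; BH-adjusted
    across sets. Rows sorted by (p, set name).
    """
    extra = selected - universe
    if extra:
        raise ValueError(f"selected genes outside the universe: {sorted(extra)[:5]}")
    restricted = sets.restrict(universe)
    n_sel = len(selected)
    n_uni = len(universe)
    rows = []
    for name in restricted.names():
        members = restricted.sets[name]
        k = len(members & selected)
        big_k = len(members)
        p = float(stats.hypergeom.sf(k - 1, n_uni, big_k, n_sel))
        rows.append({"set": name, "k": k, "K": big_k, "n": n_sel, "N": n_uni, "p": min(p, 1.0)})
    if not rows:
        return pd.DataFrame(columns=["set", "k", "K", "n", "N", "p", "q"])
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(np.clip(out["p"].to_numpy(), np.nextafter(0, 1), 1.0))
    return out.sort_values(["p", "set"], kind="mergesort").reset_index(drop=True)


def induction_attenuation(
    de_contrast1: DEResult, de_contrast2: DEResult, gene_subset: list[str]
) -> tuple[pd.DataFrame, float, float]:
    """Per-gene fold-change comparison between two contrasts.

    Returns (table with lfc1, lfc2, delta = lfc1 - lfc2; median delta; sign
    test p). The sign test is a two-sided exact binomial on the sign of delta
    with zeros dropped — delta > 0 for most genes means contrast 2 induces
    these genes less than contrast 1 does (attenuation).
    """
    t1 = de_contrast1.table.set_index("gene")
    t2 = de_contrast2.table.set_index("gene")
    missing = [g for g in gene_subset if g not in t1.index or g not in t2.index]
    if missing:
        raise KeyError(f"genes missing from a contrast: {missing[:5]}")
    lfc1 = t1.loc[gene_subset, "log2_fc"].to_numpy()
    lfc2 = t2.loc[gene_subset, "log2_fc"].to_numpy()
    delta = lfc1 - lfc2
    table = pd.DataFrame({"gene": gene_subset, "lfc1": lfc1, "lfc2": lfc2, "delta": delta})
    nonzero = delta[delta != 0]
    if nonzero.size == 0:
        p = 1.0
    else:
        p = float(stats.binomtest(int((nonzero > 0).sum()), nonzero.size, 0.5).pvalue)
    return table, float(np.median(delta)), p
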