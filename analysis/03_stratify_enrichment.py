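"""Melanoma-cohort stratification: high vs low MBNL1 tercile.

Splits the simulated SKCM cohort into MBNL1 terciles, runs differential
expression (high vs low), and tests the immune-linked gene block for
over-representation among up-regulated genes and for rank enrichment —
the expected signature when MBNL1 tracks the infiltration factor.
Outputs in results/stratification/: de.tsv, enrichment.tsv, rank_plot.tsv.
"""

from pathlib import Path

from immunoscape.io import GeneSetCollection, read_expression_matrix, write_gene_sets
from immunoscape.scores import single_gene_proxy
from immunoscape.stratify import (
    differential_expression,
    enrichment_hypergeometric,
    rank_plot_data,
    tercile_stratify,
)

IN = "scratch/inputs"
OUT = Path("results/stratification")


def immune_gene_sets(genes: list[str]) -> GeneSetCollection:
    """Synthetic gene-set collection over the simulated universe: the
    infiltration-linked block vs a same-size null block."""
    immune = {g for g in genes if g.startswith(("IMM", "GZMB", "PRF1", "CD8A"))
              or g in {"IFNG", "B2M", "GZMA", "CD274"}}
    nulls = sorted(g for g in genes if g.startswith("NULL"))[: len(immune)]
    return GeneSetCollection(
        {"IMMUNE_LINKED": immune, "NULL_BLOCK": set(nulls)},
        {"IMMUNE_LINKED": "genes loading on the infiltration factor",
         "NULL_BLOCK": "size-matched null genes"},
    )


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    matrix = read_expression_matrix(f"{IN}/matrix.tsv", f"{IN}/metadata.tsv")
    skcm = matrix.subset_cohort("SKCM")

    labels = tercile_stratify(single_gene_proxy(skcm, "MBNL1", scale="tpm").values)
    high = list(labels.index[labels == "high"])
    low = list(labels.index[labels == "low"])
    de = differential_expression(skcm, high, low, pseudocount=1.0)
    de.table.to_csv(OUT / "de.tsv", sep="\t", index=False, float_format="%.6g")

    sets = immune_gene_sets(matrix.gene_ids)
    write_gene_sets(sets, OUT / "gene_sets.gmt")
    universe = set(de.table["gene"])
    # selection for over-representation uses unadjusted p: with a weak
    # single-cohort effect and 2,000 genes, BH leaves almost nothing, while
    # the enrichment statistic itself accounts for the selection size
    upregulated = set(de.table.loc[(de.table["log2_fc"] > 0) & (de.table["p"] < 0.05), "gene"])
    print(f"SKCM high vs low MBNL1 tercile: |high| = {len(high)}, |low| = {len(low)}, "
          f"{len(upregulated)} genes up at p < 0.05")
    enr = enrichment_hypergeometric(upregulated, sets, universe)
    enr.to_csv(OUT / "enrichment.tsv", sep="\t", index=False, float_format="%.6g")
    for _, row in enr.iterrows():
        print(f"  {row['set']}: k/K = {row['k']}/{row['K']}, p = {row['p']:.3g}, q = {row['q']:.3g}")

    highlight = sets.sets["IMMUNE_LINKED"] & universe
    tab, p_rank = rank_plot_data(de, highlight)
    tab.to_csv(OUT / "rank_plot.tsv", sep="\t", index=False, float_format="%.6g")
    print(f"rank enrichment of the immune-linked block: p = {p_rank:.3g}")


if __name__ == "__main__":
    main()
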