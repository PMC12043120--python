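"""Pooled CRISPR-screen re-analysis: who survives T-cell pressure?

CPM-normalises the simulated screen counts, computes per-guide log10
fold-changes (selected vs control), aggregates to gene scores, and checks
that the planted resistance hierarchy (B2m > Mbnl1 > Mbnl2 > background)
is resolved in the ranking. Outputs in results/screen/.
"""

import pandas as pd

from immunoscape.pipeline import ScreenConfig, run_screen

IN = "scratch/inputs"
OUT = "results/screen"


def main() -> None:
    out = run_screen(ScreenConfig(
        counts_path=f"{IN}/screen_counts.tsv", mapping_path=f"{IN}/guide_map.tsv",
        out_dir=OUT,
    ))
    genes = pd.read_csv(out / "gene_table.tsv", sep="\t").set_index("gene")
    for g in ("B2m", "Mbnl1", "Mbnl2"):
        print(f"{g}: gene_score = {genes.loc[g, 'gene_score']:.3f} "
              f"(rank {genes.loc[g, 'rank']} of {len(genes)})")
    ordered = genes.loc[["B2m", "Mbnl1", "Mbnl2"], "rank"].is_monotonic_increasing
    print("planted hierarchy resolved (B2m > Mbnl1 > Mbnl2):", bool(ordered))


if __name__ == "__main__":
    main()
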