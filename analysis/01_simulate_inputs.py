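"""Generate the synthetic study inputs.

Writes the TCGA-like pan-cancer expression matrix (29 cohorts, 9,045
samples, 2,000 genes with planted infiltration structure) and a pooled
CRISPR-screen count table with planted resistance genes (B2m-like strong
hit, Mbnl1/Mbnl2-like intermediate hits). Large intermediates go to
scratch/; downstream scripts read them from there.
"""

import sys
from pathlib import Path

from immunoscape.io import write_expression_matrix, write_screen_counts
from immunoscape.simulate import (
    ScreenSimConfig,
    simulate_pan_cancer,
    simulate_screen,
    tcga_like_config,
)

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0
OUT = Path("scratch/inputs")

# screen conditions: strong antigen-presentation hit plus two intermediate
# RNA-binding-protein hits, mirroring the selection pattern the pipeline
# should resolve
SCREEN_GENES = ["B2m", "Mbnl1", "Mbnl2"] + [f"GENE{i:04d}" for i in range(997)]
SCREEN_EFFECTS = {"B2m": 8.0, "Mbnl1": 4.0, "Mbnl2": 2.5}


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    matrix, truth = simulate_pan_cancer(tcga_like_config(SEED))
    write_expression_matrix(matrix, OUT / "matrix.tsv", OUT / "metadata.tsv")
    truth.to_csv(OUT / "pancancer_truth.tsv", sep="\t", index=False)
    print(f"pan-cancer matrix: {len(matrix.gene_ids)} genes x {matrix.n_samples()} samples "
          f"across {len(matrix.cohorts)} cohorts -> {OUT}")

    cfg = ScreenSimConfig(
        genes=SCREEN_GENES, guides_per_gene=4, library_size=10_000_000,
        dispersion=0.1, resistance_effect=SCREEN_EFFECTS, seed=SEED,
    )
    table, truth = simulate_screen(cfg)
    write_screen_counts(table, OUT / "screen_counts.tsv", OUT / "guide_map.tsv")
    truth.to_csv(OUT / "screen_truth.tsv", sep="\t", index=False)
    print(f"screen counts: {len(table.guide_ids)} guides, planted effects {SCREEN_EFFECTS}")


if __name__ == "__main__":
    main()
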