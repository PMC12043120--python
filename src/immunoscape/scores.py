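"""Per-sample tumor immune-infiltration proxies.

Two proxies are supported: bulk CD8A expression (single-gene proxy for
cytotoxic T-cell infiltration) and the cytolytic activity (CYT) score, the
geometric mean of the two cytolytic effectors granzyme B (GZMB) and perforin
(PRF1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ExpressionMatrix

__all__ = ["InfiltrationVector", "single_gene_proxy", "cyt_score", "DEFAULT_PSEUDOCOUNT"]

#: default CYT pseudocount (TPM); keeps zero-expression samples finite and near zero
DEFAULT_PSEUDOCOUNT = 0.01


@dataclass
class InfiltrationVector:
    """A per-sample infiltration proxy with its name and scale ('tpm' or 'log2p1')."""

    values: pd.Series
    proxy_name: str
    scale: str

    def __post_init__(self) -> None:
        if self.scale not in ("tpm", "log2p1"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("proxy values must be finite")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)


def single_gene_proxy(matrix: ExpressionMatrix, gene: str, scale: str = "log2p1") -> InfiltrationVector:
    """Extract one gene's row as an infiltration proxy, optionally log2(TPM+1)."""
    if gene not in matrix.values.index:
        raise KeyError(f"gene {gene!r} not present in the expression matrix")
    row = matrix.values.loc[gene].astype(float)
    if scale == "log2p1":
        row = np.log2(row + 1.0)
    elif scale != "tpm":
        raise ValueError(f"unknown scale {scale!r}")
    return InfiltrationVector(row, proxy_name=gene, scale=scale)


def cyt_score(
    matrix: ExpressionMatrix,
    gzmb_id: str = "GZMB",
    prf1_id: str = "PRF1",
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> InfiltrationVector:
    """Cytolytic activity score: sqrt((GZMB + c) * (PRF1 + c)) per sample, TPM scale."""
    for g in (gzmb_id, prf1_id):
        if g not in matrix.values.index:
            raise KeyError(f"gene {g!r} not present in the expression matrix")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    gzmb = matrix.values.loc[gzmb_id].astype(float)
    prf1 = matrix.values.loc[prf1_id].astype(float)
    score = np.sqrt((gzmb + pseudocount) * (prf1 + pseudocount))
    return InfiltrationVector(score, proxy_name="CYT", scale="tpm")
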