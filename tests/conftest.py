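import numpy as np
import pandas as pd
import pytest

from immunoscape.io import ExpressionMatrix, ScreenCountTable


@pytest.fixture
def toy_matrix() -> ExpressionMatrix:
    """4 genes x 6 samples over two cohorts, hand-pickable TPM values."""
    values = pd.DataFrame(
        {
            "A-01": [0.0, 4.0, 9.0, 1.0],
            "A-02": [1.0, 4.0, 9.0, 2.0],
            "A-03": [3.0, 4.0, 9.0, 3.0],
            "B-01": [2.0, 1.0, 0.0, 4.0],
            "B-02": [5.0, 2.0, 1.0, 5.0],
            "B-03": [8.0, 3.0, 4.0, 6.0],
        },
        index=["CD8A", "GZMB", "PRF1", "G1"],
    )
    cohort_of = pd.Series(
        ["A", "A", "A", "B", "B", "B"], index=values.columns, name="cohort"
    )
    return ExpressionMatrix(values, cohort_of)


@pytest.fixture
def toy_screen() -> ScreenCountTable:
    counts = pd.DataFrame(
        {"control": [100, 110, 50, 40], "selected": [400, 450, 45, 50]},
        index=pd.Index(["B2m_g1", "B2m_g2", "Ctrl_g1", "Ctrl_g2"], name="guide"),
    )
    gene_of = pd.Series(["B2m", "B2m", "Ctrl", "Ctrl"], index=counts.index, name="gene")
    return ScreenCountTable(counts, gene_of)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
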