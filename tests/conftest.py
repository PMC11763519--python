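import numpy as np
import pandas as pd
import pytest

from orsite import AlignmentSet


@pytest.fixture
def toy_alignment() -> AlignmentSet:
    """Five short receptors; REF is ungapped so position == column."""
    return AlignmentSet(
        ["REF", "A1", "A2", "B1", "B2"],
        [
            "MLKTY",
            "MLKTY",
            "MIKTY",
            "ML-TW",
            "MXKTY",
        ],
    )


@pytest.fixture
def toy_de_table() -> pd.DataFrame:
    """Six-row worked example spanning both cutoff boundaries."""
    return pd.DataFrame(
        {
            "gene_id": [f"g{i}" for i in range(1, 7)],
            "log2fc": [-1.5, -1.0, -2.0, 1.2, -0.9, -1.1],
            "p_value": [0.01, 0.04, 0.06, 0.01, 0.01, 0.049],
        }
    )


@pytest.fixture
def small_plate() -> pd.DataFrame:
    rows = []
    for construct, conc, responses in [
        ("OR", 0.0, [1.0, 1.1, 0.9]),
        ("OR", 200.0, [2.0, 2.2, 1.9]),
        ("NoOR", 0.0, [1.0, 1.0, 1.0]),
        ("NoOR", 200.0, [1.0, 1.05, 0.95]),
    ]:
        for rep, r in enumerate(responses, start=1):
            rows.append((construct, conc, rep, r * 1000.0, 1000.0))
    return pd.DataFrame(
        rows, columns=["construct", "concentration_uM", "replicate", "firefly", "renilla"]
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
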