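import numpy as np
import pytest
from hypothesis import settings

import polcoherence as pc

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def panel():
    return pc.default_marker_panel()


@pytest.fixture
def toy_matrix():
    """4 cells × 3 genes with values straddling every TPM tier."""
    values = np.array(
        [
            [0.0, 0.05, 150.0],
            [0.05, 0.5, 120.0],
            [5.0, 5.0, 0.0],
            [20.0, 50.0, 0.5],
        ]
    )
    return pc.ExpressionMatrix(
        values, ["c1", "c2", "c3", "c4"], ["Arg1", "Tnf", "Il4ra"]
    )


@pytest.fixture
def two_gene_panel():
    return pc.MarkerPanel({"a": "M(IL4)", "b": "M(LPS,IFNγ)"})


def random_matrix(seed, n_cells=6, n_genes=4):
    rng = np.random.default_rng(seed)
    vals = np.round(rng.lognormal(0.0, 2.0, (n_cells, n_genes)), 6)
    vals[rng.random(vals.shape) < 0.3] = 0.0
    return pc.ExpressionMatrix(
        vals,
        [f"cell{i}" for i in range(n_cells)],
        [f"g{j}" for j in range(n_genes)],
    )
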