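import numpy as np
import pandas as pd
import pytest

from elbp import LabeledExpression, SyntheticConfig, generate


@pytest.fixture
def tiny_expr() -> LabeledExpression:
    """4 genes x 6 cells, two cell types, hand-checkable counts."""
    counts = np.array(
        [
            [5, 4, 6, 0, 1, 0],   # GA: high in type X
            [0, 1, 0, 7, 5, 6],   # GB: high in type Y
            [2, 2, 2, 2, 2, 2],   # GC: flat
            [0, 0, 0, 0, 0, 1],   # GD: nearly absent
        ]
    )
    cells = [f"c{i}" for i in range(6)]
    return LabeledExpression(
        counts=counts,
        gene_ids=pd.Index(["GA", "GB", "GC", "GD"]),
        cell_ids=pd.Index(cells),
        cell_type=pd.Series(["X", "X", "X", "Y", "Y", "Y"], index=cells),
        sample_id=pd.Series(["s1", "s2", "s1", "s2", "s1", "s2"], index=cells),
    )


@pytest.fixture(scope="session")
def default_bundle():
    """One generated dataset at the default configuration (rho=0.9)."""
    return generate(SyntheticConfig(), seed=11)


@pytest.fixture(scope="session")
def small_bundle():
    """A faster bundle for pipeline-level tests."""
    cfg = SyntheticConfig(cells_per_type=80, n_genes=250, n_noise_pathways=2)
    return generate(cfg, seed=5)
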