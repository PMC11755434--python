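import numpy as np
import pandas as pd
import pytest

from emstate import (
    CellMetadata,
    ExpressionMatrix,
    ScenarioConfig,
    scenario_panels,
    score_cells,
    simulate,
)

# hand matrix: 2 MES genes, 3 EPITH genes, 1 background gene; 4 cells
TINY_GENES = ["SNAI1", "FN1", "CDH1", "KRT8", "KRT18", "BG0001"]
TINY_CELLS = ["c1", "c2", "c3", "c4"]
TINY_VALUES = np.array(
    [
        [3.0, 0.0, 1.0, 2.5],   # SNAI1
        [1.0, 0.0, 2.0, 0.5],   # FN1
        [2.0, 4.0, 0.0, 1.0],   # CDH1
        [4.0, 2.0, 0.0, 3.0],   # KRT8
        [0.0, 3.0, 0.0, 2.0],   # KRT18
        [5.0, 5.0, 5.0, 5.0],   # BG0001
    ]
)


@pytest.fixture
def tiny_matrix():
    return ExpressionMatrix(list(TINY_GENES), list(TINY_CELLS),
                            TINY_VALUES.copy())


@pytest.fixture
def tiny_meta():
    return CellMetadata(pd.DataFrame({
        "cell_id": TINY_CELLS,
        "cell_type": ["A", "A", "B", "B"],
        "tissue_class": ["epithelial"] * 4,
        "organ": ["lung"] * 4,
    }))


@pytest.fixture(scope="session")
def adult_sim():
    """Moderate adult-tissue simulation shared across tests."""
    config = ScenarioConfig(n_cells=300, seed=11)
    matrix, meta = simulate(config)
    scores = score_cells(matrix, meta, scenario_panels("adult_tissue"))
    return config, matrix, meta, scores
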