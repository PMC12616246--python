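import numpy as np
import pandas as pd
import pytest

from phenoscape.celltable import CellTable
from phenoscape.synthetic import (
    CytometrySimConfig,
    ScrnaSimConfig,
    generate_cytometry_experiment,
    generate_scrna_counts,
)


@pytest.fixture
def toy_table() -> CellTable:
    """Six cells, two markers, two batches, raw scale."""
    data = pd.DataFrame(
        {
            "pSTAT3": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
            "cPARP": [0.0, 0.5, 10.0, 0.1, 20.0, 0.2],
            "condition": ["a"] * 3 + ["b"] * 3,
            "batch": ["b1", "b1", "b1", "b2", "b2", "b2"],
        }
    )
    return CellTable(data=data, channel_roles={"pSTAT3": "PTM", "cPARP": "state"})


@pytest.fixture(scope="session")
def shifted_experiment():
    """Two-condition screen with a planted arcsinh-scale shift of 1.0."""
    config = CytometrySimConfig(
        conditions=["control", "treated"],
        cells_per_condition=5000,
        shift_map={("treated", "pSTAT3"): 1.0},
        seed=11,
    )
    return generate_cytometry_experiment(config)


@pytest.fixture(scope="session")
def scrna_experiment():
    config = ScrnaSimConfig(n_cells=2000, seed=5)
    return generate_scrna_counts(config)
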