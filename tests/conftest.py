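import logging

import numpy as np
import pandas as pd
import pytest

from ctmatch.synthetic import SimulationConfig, generate_landscape

logging.getLogger("ctmatch").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_landscape():
    """One 600-tract landscape shared across tests (read-only)."""
    cfg = SimulationConfig(n_tracts=600, grid_shape=(30, 20), seed=11)
    tracts, adjacency, truth = generate_landscape(cfg)
    return cfg, tracts, adjacency, truth


@pytest.fixture()
def toy_tracts():
    """Three tracts in two municipalities for merge hand-traces.

    A (30 km², M1) borders B (5 km shared) and C (9 km shared); only B is
    in A's municipality.
    """
    tracts = pd.DataFrame(
        {
            "tract_id": ["A", "B", "C"],
            "state": ["S1"] * 3,
            "municipality": ["M1", "M1", "M2"],
            "area_km2": [30.0, 100.0, 200.0],
            "n_households": [10, 40, 50],
            "pop_count": [35, 140, 175],
            "literacy_rate": [50.0, 80.0, 60.0],
        }
    )
    adjacency = pd.DataFrame(
        {
            "tract_id": ["A", "B", "A", "C", "B", "C"],
            "neighbor_id": ["B", "A", "C", "A", "C", "B"],
            "border_km": [5.0, 5.0, 9.0, 9.0, 3.0, 3.0],
        }
    )
    return tracts, adjacency
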