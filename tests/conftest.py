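import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from fcaccess.core import DemandSet, SupplySet
from fcaccess.decay import DecayParams
from fcaccess.network import TravelTimeMatrix

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def params30() -> DecayParams:
    """Default study decay: 30-minute catchment, weight floor 0.01."""
    return DecayParams.from_threshold(30.0, 0.01)


@pytest.fixture
def tiny_system():
    """Two demand cells, three supply sites, hand-checkable travel times."""
    D = DemandSet(
        pd.DataFrame(
            {"id": ["i1", "i2"], "x": [0.0, 100.0], "y": [0.0, 0.0], "pop": [120.0, 80.0]}
        )
    )
    S = SupplySet(
        pd.DataFrame(
            {
                "id": ["j1", "j2", "j3"],
                "x": [0.0, 50.0, 200.0],
                "y": [10.0, 0.0, 0.0],
                "capacity": [2.0, 1.0, 3.0],
            }
        )
    )
    T = TravelTimeMatrix(
        pd.DataFrame(
            {
                "demand_id": ["i1", "i1", "i1", "i2", "i2"],
                "supply_id": ["j1", "j2", "j3", "j2", "j3"],
                "minutes": [2.0, 10.0, 25.0, 5.0, 15.0],
            }
        ),
        d_max=30.0,
    )
    return T, S, D


def uniform_distance_system(n_d: int, n_s: int, d: float, d_max: float):
    """Every pair at the same distance: the closed-form benchmark system."""
    rng = np.random.default_rng(7)
    D = DemandSet(
        pd.DataFrame(
            {
                "id": [f"i{k}" for k in range(n_d)],
                "x": 0.0,
                "y": 0.0,
                "pop": rng.integers(1, 400, n_d).astype(float),
            }
        )
    )
    S = SupplySet(
        pd.DataFrame(
            {
                "id": [f"j{k}" for k in range(n_s)],
                "x": 0.0,
                "y": 0.0,
                "capacity": rng.integers(1, 8, n_s).astype(float),
            }
        )
    )
    rows = [(f"i{i}", f"j{j}", d) for i in range(n_d) for j in range(n_s)]
    T = TravelTimeMatrix(
        pd.DataFrame(rows, columns=["demand_id", "supply_id", "minutes"]), d_max=d_max
    )
    return T, S, D
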