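import numpy as np
import pandas as pd
import pytest

from dmscore.model import CompartmentState, ModelParams
from dmscore.sampling import IndividualTable


@pytest.fixture
def adult_state() -> CompartmentState:
    """1000 persons per sex in each band of the 15-79 frame, factor-free,
    non-diabetic."""
    state = CompartmentState.zeros(time=0.0)
    state.occupancy[:, 3:16, 0, 0] = 1000.0
    return state


@pytest.fixture
def null_params() -> ModelParams:
    """All rates zero (no aging either): frozen dynamics."""
    return ModelParams.from_scalars(aging_rate=0.0)


def make_table(rows: list[dict]) -> IndividualTable:
    """Individual table from explicit row dicts; missing flags default to 0."""
    defaults = {"sex": 0, "age_band": 3, "obese": 0, "smoker": 0,
                "inactive": 0, "diabetic": 0}
    data = pd.DataFrame([{**defaults, **r} for r in rows])
    data.insert(0, "id", np.arange(len(data)))
    return IndividualTable(data)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260920)
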