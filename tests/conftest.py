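import numpy as np
import pandas as pd
import pytest

from healthnet import IndicatorPanel, StudyAreaSpec, generate_study_area


@pytest.fixture(scope="session")
def default_study():
    """The default 64-city study area (seed 1), shared across tests."""
    return generate_study_area(StudyAreaSpec(seed=1))


def make_panel(values: dict[str, list[float]], directions: dict[str, int],
               cities=("A", "B", "C"), years=(2005, 2006, 2007),
               agglomeration="R") -> IndicatorPanel:
    """Small hand-built panel; each indicator's list runs city-major."""
    idx = pd.MultiIndex.from_product([cities, years], names=["city", "year"])
    frame = pd.DataFrame({k: np.asarray(v, float) for k, v in values.items()}, index=idx)
    membership = pd.Series(agglomeration, index=list(cities))
    return IndicatorPanel(values=frame, directions=directions, membership=membership)


@pytest.fixture
def tiny_panel():
    # one indicator per direction, 3 cities x 3 years
    vals = {
        "pos": [1, 2, 3, 4, 5, 6, 7, 8, 9],
        "neg": [9, 8, 7, 6, 5, 4, 3, 2, 1],
    }
    return make_panel(vals, {"pos": 1, "neg": -1})
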