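import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def study_prevalence():
    from pomediate.reference import study_prevalence

    return study_prevalence()


@pytest.fixture(scope="session")
def uniform_prevalence():
    from pomediate.record_prep import PrevalenceTable

    return PrevalenceTable.from_percentages([25, 25, 25, 25], [25, 25, 25, 25])


@pytest.fixture
def toy_cells():
    """Small hand-sized eight-cell table with uneven counts."""
    from pomediate.record_prep import CellCounts

    r = np.array([[[3, 10], [7, 2]], [[5, 1], [9, 4]]])
    n = np.array([[[10, 30], [20, 12]], [[15, 9], [22, 40]]])
    return CellCounts(r, n, outcome="toy")
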