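import numpy as np
import pytest

from osteomir.io_formats import ExpressionMatrix, SampleAnnotation
from osteomir.synthetic_data import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort shared by read-only tests."""
    return simulate_cohort(SimulationConfig(seed=0))


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Zero measurement noise, 2-log2-unit planted effects: closed-form limits."""
    return simulate_cohort(SimulationConfig(seed=0, noise_sd=0.0, de_log2_effect=2.0))


@pytest.fixture
def small_matrix():
    return ExpressionMatrix(
        feature_ids=["A", "B"],
        sample_ids=["s1", "s2"],
        values=np.array([[1.0, 2.0], [3.0, 4.0]]),
        scale="log2",
    )


@pytest.fixture
def two_group_annotation():
    groups = {f"CL{i}": "cell_line" for i in range(1, 20)}
    groups.update({f"BO{i}": "bone" for i in range(1, 5)})
    return SampleAnnotation.from_mapping(groups)
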