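import numpy as np
import pytest

from tfdyn import (
    ExpressionSeries,
    OmicsSnapshot,
    PipelineConfig,
    ScenarioSpec,
    generate,
)


@pytest.fixture
def toy_snapshot() -> OmicsSnapshot:
    """Three TFs with hand-picked expression, activity and binding."""
    return OmicsSnapshot(
        time_label=0.0,
        expression={"a": 2.0, "b": 4.0, "c": 6.0},
        activity={"a": 1.0, "b": 3.0, "c": 2.0},
        binding={
            ("a", "b"): 0.9, ("a", "c"): 0.2,
            ("b", "a"): 0.5, ("b", "c"): 0.7,
            ("c", "a"): 0.1, ("c", "b"): 0.4,
        },
    )


@pytest.fixture
def toy_series() -> ExpressionSeries:
    return ExpressionSeries(
        times=np.array([0.0, 2.0, 3.0]),
        genes=["a", "b", "c"],
        values=np.array([[0.0, 5.0, 10.0],
                         [3.0, 2.0, 1.0],
                         [5.0, 5.0, 5.0]]),
    )


@pytest.fixture(scope="session")
def sparse_dataset():
    """Default random_sparse scenario, one fixed seed, shared across tests."""
    return generate(ScenarioSpec("random_sparse"), seed=1)


@pytest.fixture(scope="session")
def noisefree_dataset():
    return generate(ScenarioSpec("random_sparse", noise_sd=0.0), seed=2)


@pytest.fixture
def small_config() -> PipelineConfig:
    """Pipeline settings sized for the 8-TF synthetic benchmark."""
    return PipelineConfig(n_a=12, n_i=4, degree_top_k=20)
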