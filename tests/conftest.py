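import numpy as np
import pytest

from teaflow.core_model import DesignSpec, ExpressionMatrix


@pytest.fixture
def small_matrix() -> ExpressionMatrix:
    return ExpressionMatrix(
        ("g1", "g2", "g3"),
        ("s1", "s2"),
        np.array([[5.0, 2.0], [3.0, 4.0], [1.0, 6.0]]),
    )


@pytest.fixture
def two_group_design() -> DesignSpec:
    return DesignSpec(
        group_labels=("a", "a", "b", "b"),
        contrasts=(("b", "a"),),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
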