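import numpy as np
import pytest

from hdde.space import Factor, FactorSpace, example_space, mixed_level_space


@pytest.fixture
def space3x3() -> FactorSpace:
    """Three factors, three dose levels each (27 combinations)."""
    return mixed_level_space([3, 3, 3])


@pytest.fixture
def space15x6() -> FactorSpace:
    return example_space(15, 6)


@pytest.fixture
def space15x5() -> FactorSpace:
    return example_space(15, 5)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(0)


def make_space(level_counts) -> FactorSpace:
    return mixed_level_space(level_counts)
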