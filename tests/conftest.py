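import numpy as np
import pytest

from polbiref import PolarizationMap, StokesVector


@pytest.fixture
def poincare_states() -> np.ndarray:
    """100 pure states sampled over the Poincare sphere (deterministic)."""
    rng = np.random.default_rng(1234)
    v = rng.normal(size=(100, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return np.concatenate([np.ones((100, 1)), v], axis=1)


def uniform_map(state: StokesVector, shape=(32, 32)) -> PolarizationMap:
    stokes = np.broadcast_to(state.as_array(), shape + (4,)).copy()
    return PolarizationMap(stokes)


@pytest.fixture
def uniform_map_factory():
    return uniform_map
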