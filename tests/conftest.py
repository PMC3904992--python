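import numpy as np
import pytest

from shgame import GridState, Params, RunConfig, TopologySpec


@pytest.fixture
def default_params() -> Params:
    return Params(R=1.0, b=3.0, s=2.0, p_hd=0.2, p_dd=0.2)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def small_config() -> RunConfig:
    """A 20x20 Moore-r1 config cheap enough for unit tests."""
    return RunConfig(
        params=Params.with_p(0.45),
        rows=20,
        cols=20,
        rounds=10,
        seed=3,
    )


def checkerboard(rows: int, cols: int) -> GridState:
    cells = (np.add.outer(np.arange(rows), np.arange(cols)) % 2).astype(bool)
    return GridState(cells)


@pytest.fixture
def checkerboard_state() -> GridState:
    return checkerboard(10, 10)
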