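import numpy as np
import pytest

import ihcseg.nn.tensor as _tensor
from ihcseg.synth import TileSpec, generate_tile


@pytest.fixture
def float64_mode():
    """Finite-difference gradient checks need double precision."""
    prev = _tensor.get_default_dtype()
    _tensor.set_default_dtype(np.float64)
    yield
    _tensor.set_default_dtype(prev)


def make_tiles(n: int, seed0: int, size_px: int = 256,
               scenarios=("dcis", "invasive", "mixed", "normal")):
    """Deterministic mixed-scenario tile set used across tests."""
    rng = np.random.default_rng(seed0)
    tiles = []
    for i in range(n):
        scenario = scenarios[i % len(scenarios)]
        conf = frozenset()
        if rng.random() < 0.5:
            conf = frozenset({"lymphocytes"} if rng.random() < 0.5 else {"lobule"})
        tiles.append(generate_tile(TileSpec(
            size_px=size_px, scenario=scenario, confounders=conf,
            positivity=float(rng.uniform(0.1, 0.6)),
            seed=seed0 * 100000 + i)))
    return tiles


@pytest.fixture(scope="session")
def tile_set():
    return make_tiles(8, seed0=400)
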