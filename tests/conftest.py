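import numpy as np
import pytest

from memdyn.simulate import TableSimSpec, generate_feature_table, make_plan


@pytest.fixture(scope="session")
def small_table():
    """20 cells x 50 frames, 20 features with 2 planted per class."""
    spec = TableSimSpec(
        n_cells=20,
        frames_per_cell=50,
        n_features=20,
        archetype_plan=make_plan(20, speed_only=2, cmd_only=2, both=2),
        seed=11,
    )
    return generate_feature_table(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_mask_triple(rng, shape=(8, 8), density=0.45):
    """Random prev/curr/next masks; curr guaranteed non-empty."""
    while True:
        prev, curr, nxt = (rng.random(shape) < density for _ in range(3))
        if curr.any():
            return prev, curr, nxt
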