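import numpy as np
import pytest

import caniform as cf


@pytest.fixture(scope="session")
def template():
    labels, coords = cf.make_template()
    return labels, coords


@pytest.fixture(scope="session")
def symmetry():
    return cf.default_symmetry()


@pytest.fixture(scope="session")
def small_dataset():
    """A small but complete simulated dataset (views, replicates, unknowns)."""
    params = cf.SyntheticParams(
        n_dogs=25,
        n_arctic=50,
        n_eurasian=12,
        unknowns={"dog": 1, "arctic_wolf": 1, "midpoint": 1},
    )
    return cf.simulate_dataset(params, seed=42)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
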