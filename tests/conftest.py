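import numpy as np
import pytest

from gradta.splits import Split
from gradta.synthetic import SyntheticSpec, generate_dataset


@pytest.fixture(scope="session")
def small_synthetic():
    """A small labelled grid shared by split/training tests."""
    return generate_dataset(
        SyntheticSpec(n_drugs=12, n_targets=8, density=1.0, seed=42)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def full_split(n: int, seed: int = 0) -> Split:
    """Train-on-everything split used by overfit-style tests."""
    return Split(
        train=np.arange(n),
        validation=np.array([], dtype=np.int64),
        test=np.array([], dtype=np.int64),
        scenario="random",
        seed=seed,
    )
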