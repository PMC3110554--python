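import numpy as np
import pytest

from hpulse import FixtureSpec, make_tm_protein
from hpulse.data import load_lacy_1pv6, load_lacy_subhelix_starts

#: the G1 pulse positions of the crystallized LacY construct (frozen)
LACY_G1_PULSES = (
    7, 27, 43, 61, 74, 82, 89, 101, 122, 136, 153, 166, 174, 191, 205,
    220, 242, 257, 268, 290, 310, 323, 341, 359, 374, 393, 404,
)

CANONICAL = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture(scope="session")
def lacy_sequence() -> str:
    return load_lacy_1pv6()


@pytest.fixture(scope="session")
def lacy_starts() -> dict:
    return load_lacy_subhelix_starts()


@pytest.fixture()
def default_fixture():
    return make_tm_protein(FixtureSpec(seed=7))


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(CANONICAL[i] for i in rng.integers(0, len(CANONICAL), size=length))
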