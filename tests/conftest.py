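import numpy as np
import pytest

from pepadsorb.structures import Atom, Structure

ELEMENTS = ["H", "C", "N", "O", "S"]


def random_structure(rng, n, name="mol", charged=True, box=8.0):
    """A random structure for property tests (not physically meaningful)."""
    els = rng.choice(ELEMENTS, n)
    pos = rng.uniform(0.0, box, (n, 3))
    q = rng.normal(0.0, 0.2, n) if charged else [None] * n
    return Structure(
        [Atom(e, p, qi if charged else None) for e, p, qi in zip(els, pos, q)],
        name=name,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def water():
    return Structure(
        [
            Atom("O", [0.0, 0.0, 0.0], -0.8),
            Atom("H", [0.9572, 0.0, 0.0], 0.4),
            Atom("H", [-0.2399, 0.9266, 0.0], 0.4),
        ],
        name="water",
    )
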