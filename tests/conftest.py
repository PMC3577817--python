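import numpy as np
import pytest

from gramprom import (
    PropertyScale,
    builtin_scale,
    default_grammar,
    default_library,
)


@pytest.fixture(scope="session")
def library():
    return default_library()


@pytest.fixture(scope="session")
def grammar():
    return default_grammar()


@pytest.fixture(scope="session")
def base_stacking():
    return builtin_scale("base_stacking")


def make_flat_scale(k=2, direction="peak", value=1.0, extremes=None):
    """Synthetic scale: constant *value* except the words in *extremes*."""
    import itertools

    words = {"".join(w): value for w in itertools.product("acgt", repeat=k)}
    for w, v in (extremes or {}).items():
        words[w] = v
    return PropertyScale("synthetic", k, words, direction)


@pytest.fixture
def flat_peak_scale():
    return make_flat_scale(direction="peak")


def random_dna(rng, length, gc=0.4):
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(np.random.default_rng(rng).choice(list("acgt"), size=length, p=p))
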