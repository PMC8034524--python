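import warnings

import numpy as np
import pytest

from seqfst.core import ParamModel, machine, transition
from seqfst.expr import Param


@pytest.fixture(autouse=True)
def _silence_prune_warnings():
    # operations on deliberately empty/degenerate fixtures warn about the
    # zero machine; tests assert on weights, not warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture
def two_output_generator():
    """Normalized generator emitting AC with prob 0.6 and AG with prob 0.4."""
    return machine((), "ACG", ["s0", "s1", "end"], [
        transition("s0", None, "A", "s1", 1.0),
        transition("s1", None, "C", "end", 0.6),
        transition("s1", None, "G", "end", 0.4),
    ])


@pytest.fixture
def trainable_emitter():
    """Single-emission machine with a two-parameter probability group."""
    pm = ParamModel({"p": 0.5, "q": 0.5}, (("p", "q"),))
    return machine((), "AB", ["s", "end"], [
        transition("s", None, "A", "end", Param("p")),
        transition("s", None, "B", "end", Param("q")),
    ], pm)
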