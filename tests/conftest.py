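import numpy as np
import pytest

from ifacedyn.mutate import substitute_residue
from ifacedyn.synthetic_data import ToyComplexSpec, build_toy_complex, toy_complex_layout


@pytest.fixture(scope="session")
def toy_spec():
    return ToyComplexSpec(seed=0)


@pytest.fixture(scope="session")
def toy_layout(toy_spec):
    return toy_complex_layout(toy_spec)


@pytest.fixture(scope="session")
def toy_complex(toy_spec):
    """Toy two-helix complex with the Arg/(Tyr, Thr, Asp) interface triad."""
    return build_toy_complex(toy_spec)


@pytest.fixture(scope="session")
def gln_complex(toy_complex, toy_layout):
    """The toy complex after Arg -> Gln substitution at the interface."""
    chain, res_seq = toy_layout.arg
    return substitute_residue(toy_complex, chain, res_seq, "GLN")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
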