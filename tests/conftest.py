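import pytest

from ppiscreen.pharmacophore import build_hypothesis
from ppiscreen.synth import (
    LibrarySpec,
    aurora_interface_spec,
    make_library,
    make_toy_complex,
)


@pytest.fixture(scope="session")
def toy_complex():
    """The synthetic kinase/activator interface reconstruction."""
    return make_toy_complex(aurora_interface_spec())


@pytest.fixture(scope="session")
def hypothesis_(toy_complex):
    return build_hypothesis(
        toy_complex.structure,
        toy_complex.anchor,
        toy_complex.receptor,
        essential_residues=[8, 10],
    )


@pytest.fixture(scope="session")
def small_library(hypothesis_):
    return make_library(
        LibrarySpec(n_actives=8, n_decoys=12, seed=17), hypothesis_
    )
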