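import numpy as np
import pytest

from fluorff.synthetic import ToyMoleculeSpec, make_toy_molecule


@pytest.fixture(scope="session")
def toy_mono():
    """Toy fluorohydrin-like molecule: 4-carbon backbone, OH, F, H2 pair."""
    return make_toy_molecule(ToyMoleculeSpec(n_heavy=4, pattern="mono"))


@pytest.fixture(scope="session")
def toy_chain():
    """Bare 5-carbon chain used for parameter-recovery studies."""
    return make_toy_molecule(ToyMoleculeSpec(n_heavy=5, pattern="chain"))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
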