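import numpy as np
import pytest

from rigidbase.parameter_io import generate_synthetic_parameters


@pytest.fixture(scope="session")
def dna_params():
    """Complete synthetic DNA parameter set with stiffness blocks."""
    return generate_synthetic_parameters(seed=1, na_type="DNA")


@pytest.fixture(scope="session")
def rna_params():
    """Synthetic RNA parameter set (no blocks: faster, shape-only tests)."""
    return generate_synthetic_parameters(seed=1, na_type="RNA", with_blocks=False)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_spd(rng, n, extra=8):
    """Well-conditioned random SPD matrix (Wishart-style)."""
    a = rng.standard_normal((n, n + extra))
    return a @ a.T / (n + extra) + 0.1 * np.eye(n)
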