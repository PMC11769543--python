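import numpy as np
import pytest

from renalseg.phantom import generate_phantom, random_spec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def desk_case():
    """One deterministic easy desk-scale phantom (64^3 @ 1 mm)."""
    gen = np.random.default_rng(7)
    spec = random_spec(gen, preset="desk", difficulty="easy", category="small",
                       exophytic_prob=0.0)
    vol, mask = generate_phantom(spec, gen)
    return spec, vol, mask


@pytest.fixture(scope="session")
def abdomen_case():
    """One anisotropic abdomen phantom (96x96x48 @ 1.5x1.5x3 mm)."""
    gen = np.random.default_rng(21)
    spec = random_spec(gen, preset="abdomen", difficulty="easy", category="medium")
    vol, mask = generate_phantom(spec, gen)
    return spec, vol, mask
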