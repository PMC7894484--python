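import numpy as np
import pytest

from thermoshift import gen_toy_structure, select_calpha


@pytest.fixture(scope="session")
def toy():
    """Synthetic rhodopsin-scale Cα helical-bundle reference (251 residues)."""
    return gen_toy_structure()


@pytest.fixture(scope="session")
def small_toy():
    """Smaller bundle for the heavier simulation loops."""
    return gen_toy_structure(n_res=80, n_helices=2, bundle_radius=6.0)


@pytest.fixture(scope="session")
def crystal(toy):
    return select_calpha(toy)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
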