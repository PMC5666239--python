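import numpy as np
import pytest

from canalmorph.resample import SlidingScheme
from canalmorph.simulate import SimulationSpec, simulate_dataset, template_configuration


@pytest.fixture(scope="session")
def small_template():
    """Low-resolution canal template: (configuration, scheme), k = 26."""
    return template_configuration(n_canal=6, n_crus=3)


@pytest.fixture(scope="session")
def toy_scheme_k6():
    """k=6 toy: anchors 0-4 fixed, landmark 5 slides on a curve from 0 to 1."""
    return SlidingScheme(fixed_indices=(0, 1, 2, 3, 4),
                         curves=[("toy", (5,), (0, 1))])


@pytest.fixture(scope="session")
def toy_config_k6():
    rng = np.random.default_rng(99)
    ref = rng.normal(size=(6, 3))
    ref -= ref.mean(axis=0)
    ref /= np.linalg.norm(ref)
    return ref


@pytest.fixture(scope="session")
def small_simulation():
    """Small end-to-end dataset: 12 species x 2, low-res landmarks."""
    return simulate_dataset(SimulationSpec(
        n_species=12, n_per_species=2, n_unique=2, n_fossils=2,
        n_canal=6, n_crus=3, tree_seed=3, trait_seed=4))
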