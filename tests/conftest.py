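import numpy as np
import pytest

import hayspec as hs


@pytest.fixture(scope="session")
def small_dataset():
    """A 60-sample dataset with default physics, reused across tests."""
    return hs.make_dataset(n=60, seed=11)


@pytest.fixture(scope="session")
def noiseless_dataset():
    """Pure Beer-Lambert mixtures: no noise, no baseline, no nuisance terms."""
    noise = hs.NoiseParams(additive_sd=0, scatter_sd=0, baseline_slope_sd=0,
                           group2_fraction=0.0, replicate_sd=0,
                           group2_slope=0.0, nuisance_sd=0.0)
    comp = hs.sample_compositions(25, seed=3)
    pure = hs.pure_component_spectra()
    return hs.synthesize_reflectance(comp, pure, noise, seed=3), pure


@pytest.fixture
def rng():
    return np.random.default_rng(42)
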