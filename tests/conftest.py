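import numpy as np
import pytest

from ripacal.calibration import calibrate
from ripacal.synthetic import SyntheticSiteConfig, make_site


@pytest.fixture(scope="session")
def small_site():
    """A modest synthetic site shared by pipeline-level tests."""
    cfg = SyntheticSiteConfig(n_cells=4000, years=20, master_seed=11)
    return make_site(cfg)


@pytest.fixture(scope="session")
def small_site_results(small_site):
    return calibrate(small_site.classes, omega=small_site.config.omega)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
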