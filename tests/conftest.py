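import numpy as np
import pytest

from drspipe import (ForwardModelConfig, PopulationSpec, SHORT_SDD,
                     simulate_dataset)

COARSE_GRID = np.arange(350.0, 1921.0, 5.0)
FINE_GRID = np.arange(350.0, 1921.0, 1.0)


@pytest.fixture(scope="session")
def coarse_cfg():
    """Forward-model config on a 5-nm grid (keeps simulations fast)."""
    return ForwardModelConfig(grid=COARSE_GRID)


@pytest.fixture(scope="session")
def small_contrast_dataset(coarse_cfg):
    """Default tumor/mucosa contrast, reduced cohort: 20 patients x 10 sites."""
    spec = PopulationSpec(n_patients=20, sites_per_patient_per_class=10, seed=42)
    return simulate_dataset(spec, SHORT_SDD, coarse_cfg)


@pytest.fixture(scope="session")
def small_null_dataset(coarse_cfg):
    """Null scenario (identical class means), reduced cohort."""
    spec = PopulationSpec(n_patients=20, sites_per_patient_per_class=10,
                          seed=7).null_scenario()
    return simulate_dataset(spec, SHORT_SDD, coarse_cfg)
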