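import numpy as np
import pytest

from reimsdx.preprocessing import preprocess_cohort
from reimsdx.synthetic_data import SimulationConfig, build_reference_panel, simulate_cohort


@pytest.fixture(scope="session")
def panel():
    return build_reference_panel()


@pytest.fixture(scope="session")
def small_cohort():
    """A small but fully structured cohort: 8 normal / 7 cancer patients."""
    cfg = SimulationConfig(n_normal_patients=8, n_cancer_patients=7, seed=7)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_features(small_cohort):
    spectra, manifest = small_cohort
    features, reports, drifts = preprocess_cohort(spectra, manifest)
    return features


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
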