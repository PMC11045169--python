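import numpy as np
import pytest

import drsmargin as dm


@pytest.fixture(scope="session")
def small_config() -> dm.SimulationConfig:
    return dm.SimulationConfig(
        n_patients=12, locations_per_patient=4, tumor_location_rate=0.25, seed=11
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return dm.simulate_cohort(small_config)


@pytest.fixture(scope="session")
def small_tensor(small_cohort):
    from drsmargin.models import spectra_tensor

    measurements, _ = small_cohort
    return spectra_tensor(measurements)


@pytest.fixture(scope="session")
def small_labels(small_cohort):
    _, truths = small_cohort
    return np.array([1 if t.label == "malignant" else 0 for t in truths])


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def flat_reference():
    """MSC reference with enough structure for a well-conditioned fit."""
    from drsmargin.preprocess import ANALYSIS_WAVELENGTHS, MSCReference

    m = 0.5 + 0.3 * np.sin(ANALYSIS_WAVELENGTHS / 120.0) + 1e-4 * ANALYSIS_WAVELENGTHS
    return MSCReference(mean_intensities=m, n_contributing=10)
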