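import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from flimcontrast.synthetic import CohortSpec, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Six-patient cohort at desk scale (8x8 images, 40-sample channels)."""
    spec = CohortSpec(n_benign=3, n_malignant=3, image_size=(8, 8),
                      channel_length=40, class_effect=0.2,
                      patient_effect=0.05, noise_scale=0.02, seed=11)
    return spec, simulate_cohort(spec)


@pytest.fixture(scope="session")
def tiny_image(small_cohort):
    _, patients = small_cohort
    return patients[0].lesion


@pytest.fixture
def rng():
    return np.random.default_rng(20240)
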