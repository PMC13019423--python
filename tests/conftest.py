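import numpy as np
import pytest

from evspec.preprocess import preprocess_pipeline
from evspec.qc import run_qc
from evspec.synthetic import default_config, generate_dataset

PROFILE_SEED = 17


@pytest.fixture(scope="session")
def profile_draw():
    """One frozen draw of the calibrated profile (3 × 40 spectra)."""
    cfg = default_config(seed=PROFILE_SEED)
    spectra, truth = generate_dataset(cfg)
    return cfg, spectra, truth


@pytest.fixture(scope="session")
def profile_preprocessed(profile_draw):
    """QC survivors of the profile draw, baseline-corrected and normalised."""
    _, spectra, _ = profile_draw
    _, survivors = run_qc(spectra)
    return preprocess_pipeline(survivors)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
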