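import dataclasses

import numpy as np
import pytest

from srbindex import AnalysisConfig, SyntheticSpec, analyze_field
from srbindex.synthsim import generate_field_images


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_spec():
    """Control-culture field scaled down to 200 cells on a 512 px field."""
    return SyntheticSpec(field_size=(512, 512), n_cells_by_type=(154, 32, 14), seed=1)


@pytest.fixture(scope="session")
def small_field(small_spec):
    return generate_field_images(small_spec)


@pytest.fixture(scope="session")
def small_result(small_field):
    field, _ = small_field
    return analyze_field(field, AnalysisConfig())


@pytest.fixture(scope="session")
def clean_spec(small_spec):
    """Noise-free, background-free variant for exact-identity checks."""
    return dataclasses.replace(small_spec, noise_sd=0.0, background=(0.0, 0.0))


@pytest.fixture(scope="session")
def clean_field(clean_spec):
    return generate_field_images(clean_spec)


@pytest.fixture(scope="session")
def zero_background_config():
    return AnalysisConfig(hoechst_background=0.0, srb_background=0.0)
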