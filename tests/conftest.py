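import numpy as np
import pytest

from gliotype.config import CohortSpec, ModelConfig
from gliotype.synthetic import generate_cohort


def small_spec(**overrides) -> CohortSpec:
    """Desk-scale phantom spec: 32^3 volumes, small lesions."""
    kwargs = dict(
        n_subjects=8,
        volume_shape=(32, 32, 32),
        lesion_radius_range=(3.0, 5.0),
        noise_sd=0.02,
        seed=0,
    )
    kwargs.update(overrides)
    return CohortSpec(**kwargs)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Eight 32^3 phantom subjects, full modalities, deterministic."""
    return generate_cohort(small_spec())


@pytest.fixture()
def tiny_model_cfg():
    """1/8-width network on 16^3 crops (float64 for tight numeric checks)."""
    return ModelConfig.scaled(0.125)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
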