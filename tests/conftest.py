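import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mifquant.synthetic import CohortSpec, PhenotypeSpec

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20210)


@pytest.fixture
def tiny_spec():
    """Two small phenotypes, deterministic counts, no noise or heterogeneity."""
    return CohortSpec(
        n_group_a=2,
        n_group_b=2,
        fovs_per_section=(2, 2),
        phenotypes=(
            PhenotypeSpec("tumor", {"CK": 1500}, {"CK": 0}, abundance=5),
            PhenotypeSpec("immune", {"CD45": 1200}, {"CD45": 0}, abundance=5),
        ),
        noise_sd=0.0,
        dapi_sd=0.0,
        section_sigma_log2=0.0,
        fixed_counts=True,
        shape=(96, 96),
        seed=11,
    )
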