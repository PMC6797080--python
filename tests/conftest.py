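import numpy as np
import pytest

from juncture.model_spec import canonical_cbt_model
from juncture.simulate import PopulationConfig, draw_population


@pytest.fixture(scope="session")
def canonical_model():
    return canonical_cbt_model()


@pytest.fixture(scope="session")
def small_model():
    """Canonical structure at desk scale: 12 orgs x 4 x 10 = 480 patients."""
    return canonical_cbt_model(
        {
            "hierarchy": {
                "organizations": 12,
                "practitioners_per_organization": 4,
                "patients_per_practitioner": 10,
            }
        }
    )


@pytest.fixture(scope="session")
def canonical_draw(canonical_model):
    config = PopulationConfig.from_model(canonical_model, seed=20240917)
    return draw_population(canonical_model, config)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
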