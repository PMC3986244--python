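import numpy as np
import pytest

from lipidcv.cohort import GeneratorConfig, generate_cohort, null_config


@pytest.fixture(scope="session")
def default_cohort():
    """Default-design cohort (23/45/45 samples, 316 species, 24 classes)."""
    return generate_cohort(GeneratorConfig(seed=20140414))


@pytest.fixture(scope="session")
def null_cohort():
    """Default-design cohort with no injected effects."""
    return generate_cohort(null_config(seed=99))


@pytest.fixture(scope="session")
def small_null_cohort():
    """Two-class, 12-species null cohort for cheap scans."""
    cfg = null_config(
        group_sizes={"HIV_CASE": 20, "HIV_CONTROL": 30, "HEALTHY": 30},
        species_per_class={"A": 6, "B": 6},
        seed=5,
    )
    return generate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
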