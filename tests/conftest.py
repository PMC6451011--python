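import numpy as np
import pytest

from somnotype.synthetic_cohort import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def big_cohort():
    """500-individual default cohort shared by the Monte-Carlo calibration
    and containment tests (generation only, no detection)."""
    cfg = GeneratorConfig(n_individuals=500, seed=2024)
    return cfg, *generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
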