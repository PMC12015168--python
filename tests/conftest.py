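import numpy as np
import pytest

from preemie_probiome.synthetic import CohortConfig, generate_cohort


def small_config(seed: int = 7, **overrides) -> CohortConfig:
    """A scaled-down cohort config for fast end-to-end tests."""
    cfg = CohortConfig(seed=seed)
    cfg.ep_elbw.n = overrides.pop("n_ep", 18)
    cfg.vp_vlbw.n = overrides.pop("n_vp", 12)
    for key, value in overrides.items():
        setattr(cfg, key, value)
    return cfg


@pytest.fixture(scope="session")
def small_cohort():
    """(infants, samples, profiles, truth) for a 30-infant cohort."""
    return generate_cohort(small_config())


@pytest.fixture(scope="session")
def default_cohort():
    """The full-size (123-infant) default cohort."""
    return generate_cohort(CohortConfig(seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
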