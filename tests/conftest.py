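import functools

import pytest
from hypothesis import settings

from cotwin.harmonize import harmonize
from cotwin.simulate import scenario, simulate_cohort

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@functools.lru_cache(maxsize=8)
def _cohort(name: str, scale: float, seed: int, ascertainment=None):
    ace, cfg = scenario(name, scale=scale, seed=seed, ascertainment=ascertainment)
    df = simulate_cohort(cfg, ace)
    return harmonize(df, ldi_cutoff=cfg.ldi_cutoff)


@pytest.fixture(scope="session")
def make_harmonized():
    """Factory returning a harmonized simulated cohort (cached across tests)."""
    return _cohort


@pytest.fixture(scope="session")
def small_genetic(make_harmonized):
    """~600-pair cohort under the genetic-confounding scenario."""
    return make_harmonized("genetic_confounding", 0.02, 3)
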