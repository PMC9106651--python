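import numpy as np
import pytest

from cnstriage.synthetic_cohort import (
    SimConfig,
    SyntheticGenome,
    generate_cohort,
    make_resources,
)


@pytest.fixture(scope="session")
def genome() -> SyntheticGenome:
    return SyntheticGenome()


@pytest.fixture(scope="session")
def resources(genome):
    return make_resources(genome)


@pytest.fixture(scope="session")
def small_cohort(resources):
    """A small case-control cohort without depth profiles, shared across
    tests that only need variant tables."""
    cfg = SimConfig(seed=42, n_cases=30, n_controls=30, make_depth=False)
    bundle, res = generate_cohort(cfg, resources)
    return bundle, res


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
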