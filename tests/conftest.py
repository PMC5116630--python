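import numpy as np
import pytest

from tvawr import CohortSpec, TVAParams
from tvawr.cli import default_designs

#: Generating parameters used throughout: threshold 14 +/- 5 ms, speed
#: 80 letters/s, capacity distribution with mean 3.9 letters.
REFERENCE_K_PROBS = (0.05, 0.10, 0.20, 0.30, 0.25, 0.10)


@pytest.fixture(scope="session")
def reference_params() -> TVAParams:
    return TVAParams(t0_mean=14.0, t0_sd=5.0, C=80.0, k_probs=REFERENCE_K_PROBS)


@pytest.fixture(scope="session")
def designs():
    """The study's two session designs (27 trials per duration each)."""
    return default_designs()


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


def random_params(rng: np.random.Generator) -> TVAParams:
    """A random but realistic parameter set for property tests."""
    k = rng.dirichlet(np.ones(6))
    return TVAParams(
        t0_mean=rng.uniform(5.0, 30.0),
        t0_sd=rng.uniform(0.5, 15.0),
        C=rng.uniform(20.0, 150.0),
        k_probs=k,
    )


@pytest.fixture(scope="session")
def small_cohort_spec() -> CohortSpec:
    return CohortSpec(n_participants=6, seed=11)
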