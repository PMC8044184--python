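import numpy as np
import pytest

from cohortsnv.model import ModelParams
from cohortsnv.simulate import CloneCohortSpec, simulate_cohort


@pytest.fixture
def params() -> ModelParams:
    return ModelParams()


@pytest.fixture(scope="session")
def small_cohort():
    """A 100-locus cohort shared by the cheaper integration tests."""
    return simulate_cohort(CloneCohortSpec(n_true_snvs=50, n_null_loci=50, seed=7))


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)
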