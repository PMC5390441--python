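import pytest

from harmonizer.logictree import AnnealingConfig
from harmonizer.rules import default_registry
from harmonizer.synth import CohortSpec, easy_suite, hard_suite


#: Small but fully heterogeneous study conditions used across tests: 6 cohorts
#: (3 construction / 3 validation), ~150 participants, 40 noise variables.
SMALL_SPEC = dict(n_participants=150, n_noise_variables=40)

#: minmass=1 because at this scale a target has only 2-3 positive training
#: instances; the search schedule is the package default.
FAST_FIT = dict(n_iterations=3000, minmass=1)


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def easy(registry):
    suite = easy_suite(n_datasets=6, seed=3, registry=registry,
                       base_spec=CohortSpec(**SMALL_SPEC))
    return suite, suite.profiles_by_dataset()


@pytest.fixture(scope="session")
def hard(registry):
    suite = hard_suite(
        n_datasets=6, seed=3, registry=registry,
        base_spec=CohortSpec(missing_rate=0.05, decoy_rate=0.9, **SMALL_SPEC),
    )
    return suite, suite.profiles_by_dataset()


@pytest.fixture
def fast_config():
    return AnnealingConfig(seed=11, **FAST_FIT)
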