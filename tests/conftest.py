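import pytest

from glioburden import (
    BetaSimSpec,
    fixture_discovery_metadata,
    fixture_setd2_variants,
    fixture_table1,
    simulate_beta_matrix,
)


@pytest.fixture(scope="session")
def table1_metadata():
    return fixture_table1()


@pytest.fixture(scope="session")
def setd2_variants():
    return fixture_setd2_variants()


@pytest.fixture(scope="session")
def discovery_metadata():
    return fixture_discovery_metadata()


@pytest.fixture()
def small_beta():
    bm, labels = simulate_beta_matrix(
        BetaSimSpec(n_samples=24, n_probes=60, k_true=2, n_informative_probes=20,
                    shift=0.4, noise_sd=0.02, seed=1)
    )
    return bm, labels
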