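import pytest

from clonotrace.examples import example_pool, papillary_tumor_example
from clonotrace.panel import default_panel
from clonotrace.simulate import simulate_library


@pytest.fixture(scope="session")
def pool33():
    """The packaged 33-construct bladder pool (balanced titers)."""
    return example_pool()


@pytest.fixture(scope="session")
def tumor3():
    """Three dominant clones, four shared events, three pure regions."""
    return papillary_tumor_example()


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def small_pool():
    return simulate_library(n_orf=3, n_shrna=3, class_imbalance=1.0, seed=7)
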