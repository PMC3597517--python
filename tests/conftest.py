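import numpy as np
import pytest

from junctionsig import generate_locus, load_table1_fixture


@pytest.fixture(scope="session")
def fixture_records():
    return load_table1_fixture()


@pytest.fixture(scope="session")
def small_locus():
    """A 120-kb synthetic locus with planted repeat cassettes."""
    return generate_locus(length=120_000, gc=0.41, repeat_density=0.2, seed=3)


@pytest.fixture(scope="session")
def uniform_locus():
    """A repeat-free iid uniform locus for analytic control checks."""
    region, _ = generate_locus(length=3_200_000, gc=0.5, repeat_density=0.0,
                               seed=11)
    return region


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
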