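import pytest

import nfootprint as nf


@pytest.fixture(scope="session")
def clean_world() -> nf.World:
    """Noiseless four-year world: pipeline must equal closed form."""
    return nf.generate_world(nf.WorldSpec(seed=11, years=(2010, 2013), noise_sigma=0.0))


@pytest.fixture(scope="session")
def noisy_world() -> nf.World:
    return nf.generate_world(nf.WorldSpec(seed=11, years=(2010, 2013), noise_sigma=0.05))


@pytest.fixture(scope="session")
def table1():
    return nf.table1_fixture()


@pytest.fixture(scope="session")
def table2():
    return nf.table2_fixture()


@pytest.fixture(scope="session")
def baseline_2013(noisy_world):
    return nf.baseline_inputs(noisy_world, 2013)
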