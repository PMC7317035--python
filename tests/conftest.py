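import numpy as np
import pytest

from lungquant import PhantomSpec, make_lung_phantom


@pytest.fixture(scope="session")
def default_phantom():
    """One default phantom bundle shared across tests (seed 0)."""
    spec = PhantomSpec(seed=0)
    short, long_, pet, mask, truth = make_lung_phantom(spec)
    return {
        "spec": spec,
        "short": short,
        "long": long_,
        "pet": pet,
        "mask": mask,
        "truth": truth,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
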