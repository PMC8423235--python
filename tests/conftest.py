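import numpy as np
import pytest

from hdcnet.synthetic_fundus import PhantomSpec, generate


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def phantom_pairs():
    """Four small seeded phantoms, shared across tests that only read them."""
    return [generate(PhantomSpec(size=(64, 64), seed=100 + i)) for i in range(4)]


@pytest.fixture(scope="session")
def phantom_dataset(tmp_path_factory):
    """A phantom dataset written to disk once per session."""
    from hdcnet.synthetic_fundus import make_dataset

    root = tmp_path_factory.mktemp("phantoms")
    spec = PhantomSpec(size=(64, 64), seed=300)
    dset = make_dataset(spec, 6, root)
    return dset, root
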