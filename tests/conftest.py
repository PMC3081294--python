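import numpy as np
import pytest

from voroscore import synthetic_fixtures as sf
from voroscore.structure_model import load_volume_table


@pytest.fixture(scope="session")
def volumes():
    return load_volume_table()


@pytest.fixture(scope="session")
def toy():
    """A 30+30-residue docked toy complex with its ground-truth manifest."""
    spec = sf.FixtureSpec(seed=3)
    native, manifest = sf.make_toy_complex(spec)
    return spec, native, manifest


@pytest.fixture(scope="session")
def toy_decoys(toy):
    spec, native, _ = toy
    return sf.make_decoy_ensemble(spec, native)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
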