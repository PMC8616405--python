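import numpy as np
import pytest

from altorf.cascade import load_bxc48_features
from altorf.discovery import KozakModel
from altorf.pipeline import run_pipeline
from altorf.simulate import default_config, make_bundle


@pytest.fixture(scope="session")
def bxc48():
    """The packaged 48-candidate BX-C feature table."""
    return load_bxc48_features()


@pytest.fixture(scope="session")
def kozak_model():
    return KozakModel.default()


@pytest.fixture(scope="session")
def default_bundle():
    """The standard synthetic bundle: 20 pass-all plants, 80 decoys."""
    return make_bundle(default_config(42))


@pytest.fixture(scope="session")
def pipeline_result(default_bundle):
    """Full pipeline run over the default bundle (computed once)."""
    return run_pipeline(default_bundle)


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])
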