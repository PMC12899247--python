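import numpy as np
import pytest

from yolowl.manifest import load_default_manifest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_manifest():
    return load_default_manifest()


@pytest.fixture(scope="session")
def built_model(default_manifest):
    """The full detector built once per session (cheap: ~1.4M params)."""
    from yolowl.assembly import build_model
    return build_model(default_manifest, rng=np.random.default_rng(0))
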