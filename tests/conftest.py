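import numpy as np
import pytest

from chemosmooth.model_core import ModelParams, medium_preset


@pytest.fixture(scope="session")
def params():
    return ModelParams()


@pytest.fixture(scope="session")
def medium():
    return medium_preset(1.7)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


class RunCache:
    """Session-wide cache of expensive simulation runs.

    Acceptance tests share base-case and sweep simulations; each run is
    built lazily on first request and reused afterwards.
    """

    def __init__(self):
        self._store = {}

    def get(self, key, builder):
        if key not in self._store:
            self._store[key] = builder()
        return self._store[key]


@pytest.fixture(scope="session")
def run_cache():
    return RunCache()
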