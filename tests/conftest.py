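import pytest

from regulatome.fixtures import load_condition_table
from regulatome.registry import load_panel, load_regulatome


@pytest.fixture(scope="session")
def registry():
    return load_regulatome()


@pytest.fixture(scope="session")
def housekeeping_panel():
    return load_panel("housekeeping")


@pytest.fixture(scope="session")
def condition(registry):
    """Loader for packaged condition fixtures, cached per session."""
    cache = {}

    def _load(name):
        if name not in cache:
            cache[name] = load_condition_table(name)
        return cache[name]

    return _load
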