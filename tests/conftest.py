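import pytest

from vrncaps import build_scaffold_set, default_registry


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def scaffolds(registry):
    """Base scaffold set at a fixed seed, shared across the suite."""
    return build_scaffold_set(1, registry)
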