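import pytest

from aahash.seed_tables import default_tables


@pytest.fixture(scope="session")
def tables():
    """Canonical three-level seed tables, built once per session."""
    return default_tables()
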