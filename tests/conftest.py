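import pytest

from nosokit.fixtures import toy_cssc_sets, toy_disorders


@pytest.fixture(scope="session")
def toy_defs():
    """The four toy disorder definitions, keyed by name."""
    return {d.name: d for d in toy_disorders()}


@pytest.fixture(scope="session")
def toy_sets():
    """The reference toy CSSC sets (Z as the two singletons), keyed by name."""
    return toy_cssc_sets()
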