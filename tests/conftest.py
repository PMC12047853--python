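import pytest

from abxminer.lexicons import default_lexicons
from abxminer.synthetic_data import GenerationConfig, generate_corpus


@pytest.fixture(scope="session")
def lex():
    return default_lexicons()


@pytest.fixture(scope="session")
def small_corpus():
    """A ~500-post synthetic corpus shared by read-only tests."""
    return generate_corpus(GenerationConfig(n_users=300, seed=1234))
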