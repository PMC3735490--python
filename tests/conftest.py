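import pytest
from hypothesis import settings

from xiscreen.simulate import default_expression_model, make_toy_genome

settings.register_profile("suite", max_examples=50, deadline=None, derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def toy():
    """Toy study inputs: genome, annotations, strain variants (seed 1)."""
    return make_toy_genome(1, 20_000, 20_000)


@pytest.fixture(scope="session")
def toy_model():
    return default_expression_model()
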