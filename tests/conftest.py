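import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")

from mitolens import reference
from mitolens.synthetic import generate_genome


@pytest.fixture(scope="session")
def cerana():
    """Annotation-only A. cerana genome from the bundled coordinate table."""
    return reference.apis_cerana_annotation()


@pytest.fixture(scope="session")
def synthetic_bundle():
    """One honeybee-plan synthetic genome plus its ground truth."""
    return generate_genome(seed=7)
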