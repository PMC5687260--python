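import hypothesis
import pytest

from codbench import default_codesets

hypothesis.settings.register_profile(
    "default", derandomize=True, deadline=None, max_examples=50
)
hypothesis.settings.load_profile("default")


@pytest.fixture(scope="session")
def codesets():
    return default_codesets()
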