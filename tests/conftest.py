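import pytest

from asictox.chemistry import AnnotationSet


@pytest.fixture(scope="session")
def ann():
    return AnnotationSet.default()
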