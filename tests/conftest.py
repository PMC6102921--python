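import pytest

from molarcea import load_reference_model


@pytest.fixture(scope="session")
def reference_spec():
    """The packaged single-molar prosthesis model."""
    return load_reference_model()


@pytest.fixture(scope="session")
def reference_traces(reference_spec):
    from molarcea import base_case

    return base_case(reference_spec)
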