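import pytest


@pytest.fixture(scope="session")
def e2e_result():
    """The full default-condition pipeline run, shared across tests."""
    from conchicore import pipeline

    return pipeline.run_end_to_end()


@pytest.fixture(scope="session")
def profiles():
    from conchicore.domain_annotation import load_profiles

    return load_profiles()
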