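import pytest

from oraldose import load_reference_compounds, load_settings


@pytest.fixture(scope="session")
def settings():
    return load_settings()


@pytest.fixture(scope="session")
def compounds():
    return {c.name: c for c in load_reference_compounds()}


@pytest.fixture(scope="session")
def diazepam(compounds):
    return compounds["Diazepam"]


@pytest.fixture(scope="session")
def chlorpromazine(compounds):
    return compounds["Chlorpromazine"]


@pytest.fixture(scope="session")
def prazosin(compounds):
    return compounds["Prazosin"]
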