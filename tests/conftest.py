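import pytest

from flavoscreen.synthetic import (
    GeneratorConfig,
    build_reference_library,
    load_panel,
    load_transitions,
    standards_registry,
)


@pytest.fixture(scope="session")
def panel():
    return load_panel()


@pytest.fixture(scope="session")
def library(panel):
    return build_reference_library(panel)


@pytest.fixture(scope="session")
def registry(panel):
    return standards_registry(panel)


@pytest.fixture(scope="session")
def transitions():
    return load_transitions()


@pytest.fixture()
def gen_cfg():
    return GeneratorConfig(seed=1)
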