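import pytest

from phido.builder import build_schema
from phido.session import compile_script
from phido.simulator import example_script


@pytest.fixture(scope="session")
def schema():
    return build_schema()


@pytest.fixture(scope="session")
def hpv_script():
    return example_script()


@pytest.fixture()
def hpv_graph(schema, hpv_script):
    """Fresh compiled session graph (engine steps mutate instances)."""
    return compile_script(hpv_script, schema)
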