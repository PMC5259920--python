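import pytest

from vtecea.analyses import run_base_case
from vtecea.parameters import default_paper_parameters
from vtecea.synthetic import default_life_table, toy_models


@pytest.fixture(scope="session")
def paper_params():
    return default_paper_parameters()


@pytest.fixture(scope="session")
def life_table():
    return default_life_table()


@pytest.fixture(scope="session")
def base_case(paper_params, life_table):
    """Deterministic base-case result shared across tests (read-only)."""
    return run_base_case(paper_params, life_table)


@pytest.fixture(scope="session")
def toys():
    return toy_models()
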