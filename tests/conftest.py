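import pytest

from rmccost.synthetic import cost_model, paper_fixture


@pytest.fixture(scope="session")
def bundle():
    """The packaged reference dataset (inventory, scenarios, population, program)."""
    return paper_fixture()


@pytest.fixture(scope="session")
def model(bundle):
    """System-level cost model assembled from the reference dataset."""
    return cost_model(bundle)
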