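import warnings

import pytest

from isgarden.datasets import demo_tables, load_insertion_catalog


@pytest.fixture(scope="session")
def catalog_events():
    """The bundled synthetic 142-clone insertion catalog."""
    return load_insertion_catalog()


@pytest.fixture(scope="session")
def demo():
    """(gardens, environment table, abundance table) for the bundled catalog."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return demo_tables(seed=0)
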