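import pytest

from crt1kit.synthetic_data import curated_missense_catalog
from crt1kit.topology import default_topology
from crt1kit.variant_analysis import annotate_table


@pytest.fixture(scope="session")
def topo():
    return default_topology()


@pytest.fixture(scope="session")
def catalog():
    return curated_missense_catalog()


@pytest.fixture(scope="session")
def annotated_catalog(catalog, topo):
    return annotate_table(catalog, topo)
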