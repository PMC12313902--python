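import numpy as np
import pytest

from topoqspr import (load_descriptors, load_drug_table, load_properties,
                      random_molecular_graph)


@pytest.fixture(scope="session")
def properties():
    return load_properties()


@pytest.fixture(scope="session")
def descriptors():
    return load_descriptors()


@pytest.fixture(scope="session")
def drug_records():
    return load_drug_table()


@pytest.fixture(scope="session")
def random_graphs():
    """A pool of 500 random bounded-degree connected graphs of varied size."""
    rng = np.random.default_rng(20240917)
    graphs = []
    for _ in range(500):
        n = int(rng.integers(2, 30))
        graphs.append(random_molecular_graph(
            n, max_degree=int(rng.integers(2, 5)),
            extra_edge_prob=float(rng.uniform(0, 0.3)), seed=rng))
    return graphs
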