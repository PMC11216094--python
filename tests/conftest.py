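import numpy as np
import pytest

from halbde.dataset import load_heterolytic, load_homolytic, non_missing
from halbde.featurize import DescriptorConfig, mol_to_graph
from halbde.registry import ReagentRegistry

GROUP_IDS = list("abcdefghijklmnopqrst")


@pytest.fixture(scope="session")
def registry():
    return ReagentRegistry.default()


@pytest.fixture(scope="session")
def homolytic_records():
    return load_homolytic()


@pytest.fixture(scope="session")
def heterolytic_records():
    return load_heterolytic()


@pytest.fixture(scope="session")
def library(registry):
    """All 300 study reagents (5 skeletons x 3 halogens x 20 groups)."""
    return registry.enumerate_reagents(range(1, 6), ["I", "Br", "Cl"], GROUP_IDS)


@pytest.fixture(scope="session")
def homolytic_graphs(registry, homolytic_records):
    """Featurized graphs keyed like the homolytic records, plus targets."""
    recs = non_missing(homolytic_records)
    config = DescriptorConfig()
    graphs = [mol_to_graph(registry.make_reagent(*r.key).smiles, config, r.key)
              for r in recs]
    targets = np.array([r.value for r in recs])
    return recs, graphs, targets
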