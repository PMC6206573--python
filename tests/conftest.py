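import networkx as nx
import pytest

from formulanet import datasets, synthetic, targets as tg


@pytest.fixture(scope="session")
def toy_ppi() -> nx.Graph:
    """The bundled 8-gene worked-example network."""
    return datasets.load_toy_ppi()


@pytest.fixture(scope="session")
def small_ppi():
    """120-node scale-free PPI with 3 planted dense modules."""
    return synthetic.gen_ppi(120, mean_degree=6.0, n_planted_modules=3, module_size=8, seed=11)


@pytest.fixture(scope="session")
def planted_profile():
    """Compound-target profile with 50 planted core targets at lift 8."""
    frame, truth = synthetic.gen_compound_targets(
        200, n_targets=1000, n_core=50, lift=8.0, seed=7
    )
    return tg.InteractionTable(frame), truth
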