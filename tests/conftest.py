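import numpy as np
import pytest

import predscale as ps


@pytest.fixture(scope="session")
def balanced_tree():
    """Fixed 5-taxon tree with known shared times."""
    return ps.read_newick("((A:1,B:1):1,(C:1.5,(D:0.5,E:0.5):1):0.5):0;")


@pytest.fixture(scope="session")
def toy_census_counts():
    return [10, 5, 3, 1, 1]


@pytest.fixture(scope="session")
def synthetic_census():
    return ps.lujiatun_like_census()


def simulate_bm_tips(phy, rng):
    """Independent branch-wise Brownian simulation oracle.

    Walks the newick structure directly: child value = parent value +
    Normal(0, branch length); returns tip values in tip_labels order.
    Deliberately does not use shared_time_matrix.
    """
    tree = phy._tree
    values = {id(tree.seed_node): 0.0}
    out = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent = values[id(node.parent_node)]
        values[id(node)] = parent + rng.normal(0.0, np.sqrt(node.edge.length or 0.0))
        if node.is_leaf():
            out[node.taxon.label] = values[id(node)]
    return np.array([out[lab] for lab in phy.tip_labels])
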