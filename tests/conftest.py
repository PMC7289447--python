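import numpy as np
import pytest

from cochap.phylo.tree import PhyloTree
from cochap.simulate import generate_yule_tree


@pytest.fixture(scope="session")
def tree4():
    return PhyloTree.from_newick("((A:0.3,B:0.5):0.2,(C:0.1,D:0.7):0.4);")


@pytest.fixture(scope="session")
def tree12():
    return generate_yule_tree(12, 2.0, 7)


@pytest.fixture(scope="session")
def tree64():
    # the coevolution study tree: 64 taxa, ~0.9 substitutions/site root-to-tip
    return generate_yule_tree(64, 4.0, 1)
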