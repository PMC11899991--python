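import itertools

import dendropy
import numpy as np
import pandas as pd
import pytest

TREE_4 = "((a:0.3,b:0.3):0.1,(c:0.3,d:0.3):0.1);"
TREE_6 = "(((a:0.2,b:0.2):0.1,(c:0.2,d:0.2):0.1):0.05,(e:0.25,f:0.25):0.05);"
TREE_8 = "(((a:0.2,b:0.2):0.1,(c:0.2,d:0.2):0.1):0.05,((e:0.2,f:0.2):0.1,(g:0.2,h:0.2):0.1):0.05);"


@pytest.fixture(scope="session")
def tree4():
    return TREE_4


@pytest.fixture(scope="session")
def tree6():
    return TREE_6


@pytest.fixture(scope="session")
def tree8():
    return TREE_8


def additive_matrix(newick: str) -> pd.DataFrame:
    """Exact leaf-to-leaf path-length matrix of a tree (the additivity oracle)."""
    tree = dendropy.Tree.get(data=newick, schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    names = sorted(t.label for t in tree.taxon_namespace)
    by_label = {t.label: t for t in tree.taxon_namespace}
    out = pd.DataFrame(0.0, index=names, columns=names)
    for x, y in itertools.combinations(names, 2):
        d = pdm.distance(by_label[x], by_label[y])
        out.loc[x, y] = out.loc[y, x] = d
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
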