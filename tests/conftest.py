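import numpy as np
import pytest

from phylofrag import _trees


@pytest.fixture
def toy_treeset():
    """Five 5-leaf trees (outgroup O) with a 3/5 vs 2/5 clade conflict."""
    newicks = ["((A,B),(C,(D,O)));"] * 3 + ["((A,C),(B,(D,O)));"] * 2
    return [_trees.parse_newick(s) for s in newicks]


@pytest.fixture
def rng():
    return np.random.default_rng(20230901)
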