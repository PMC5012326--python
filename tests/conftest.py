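import numpy as np
import pytest

from ihedge.core import Split, TaxonSet, WeightedSplitSystem


@pytest.fixture
def star3():
    """3-taxon star with pendant weights 1, 2, 3."""
    taxa = TaxonSet(["t1", "t2", "t3"])
    return WeightedSplitSystem(
        taxa, [(Split.of({i}, 3), float(i + 1)) for i in range(3)]
    )


@pytest.fixture
def quartet_newick():
    return "((A:1,B:1):1,(C:1,D:1):1);"


@pytest.fixture
def rng():
    return np.random.default_rng(20160823)
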