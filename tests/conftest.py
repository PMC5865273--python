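import random

import pytest

from taxocover.setcover import SetCoverInstance
from taxocover.taxonomy import parse_newick


@pytest.fixture
def worked_instance() -> SetCoverInstance:
    """The 12-read, 6-node instance of the worked disambiguation example:
    each read's argmax nodes induce one subset of reads per node."""
    family = {
        "y1": frozenset({"x01", "x02", "x03", "x04", "x05", "x06"}),
        "y2": frozenset({"x05", "x06", "x08", "x09"}),
        "y3": frozenset({"x01", "x04", "x07", "x10"}),
        "y4": frozenset({"x02", "x05", "x07", "x08", "x11"}),
        "y5": frozenset({"x03", "x06", "x09", "x12"}),
        "y6": frozenset({"x10", "x11"}),
    }
    elements = frozenset().union(*family.values())
    return SetCoverInstance(elements=elements, family=family)


@pytest.fixture
def two_clade_tree():
    """Root with two 4-leaf clades: candidate sequences a1..a4 spread over
    both, so annotating at the first clade gives TP=3, FP=1, TN=3, FN=1."""
    return parse_newick("((a1,a2,a3,b1)j,(a4,t1,t2,t3)k)i;")


@pytest.fixture
def rng() -> random.Random:
    return random.Random(20260929)
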