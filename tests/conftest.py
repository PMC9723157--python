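import numpy as np
import pytest
from hypothesis import settings

from phyloconcord.trees import Node, Tree

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")

# Balanced ultrametric 6-taxon species tree in coalescent units: short
# internal branches (0.5) create appreciable incomplete lineage sorting.
BALANCED_6 = "(((A:1.0,B:1.0):0.5,(C:1.0,D:1.0):0.5):0.5,(E:1.5,F:1.5):0.5);"

# Caterpillar with mixed internal branch lengths for calibration sweeps.
CATERPILLAR_6 = "(((((A:0.4,B:0.4):0.6,C:1.0):1.0,D:2.0):0.7,E:2.7):1.3,F:4.0);"

# Deep-divergence regime (long terminal branches relative to coalescent
# variance), the realistic setting for rogue-leaf detection.
DEEP_6 = "(((A:6,B:6):3,(C:6,D:6):3):3,(E:9,F:9):3);"


@pytest.fixture
def balanced_tree():
    return Tree.from_newick(BALANCED_6)


@pytest.fixture
def caterpillar_tree():
    return Tree.from_newick(CATERPILLAR_6)


@pytest.fixture
def deep_tree():
    return Tree.from_newick(DEEP_6)


def random_binary_tree(labels, rng, with_lengths=False):
    """Uniform-ish random binary topology by sequential random joins."""
    nodes = [
        Node(label=l, length=float(rng.uniform(0.05, 1.0)) if with_lengths else None)
        for l in labels
    ]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = Node(
            length=float(rng.uniform(0.05, 1.0)) if with_lengths else None
        )
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    root = nodes[0]
    root.length = None
    return Tree(root)
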