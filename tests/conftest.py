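import numpy as np
import pytest

from phyloplast.tree import Node, PhyloTree


def build_random_topology(rng, n_tips, allow_polytomies=False, with_lengths=True):
    """Random rooted topology, independent of the package's simulator:
    recursively partition the label set, optionally into >2 blocks."""
    labels = [f"t{i:03d}" for i in range(n_tips)]

    def build(lbls):
        if len(lbls) == 1:
            return Node(
                label=lbls[0],
                length=float(rng.uniform(0.1, 1.0)) if with_lengths else None,
            )
        max_k = min(4, len(lbls))
        k = int(rng.integers(2, max_k + 1)) if (allow_polytomies and max_k > 2) else 2
        # random partition into k non-empty blocks
        perm = list(rng.permutation(lbls))
        cuts = sorted(rng.choice(np.arange(1, len(lbls)), size=k - 1, replace=False))
        blocks, start = [], 0
        for c in list(cuts) + [len(lbls)]:
            blocks.append(perm[start:c])
            start = c
        node = Node(length=float(rng.uniform(0.1, 1.0)) if with_lengths else None)
        for b in blocks:
            node.add_child(build(b))
        return node

    root = build(labels)
    root.length = None
    return PhyloTree(root)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def random_topology():
    return build_random_topology
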