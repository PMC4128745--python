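import numpy as np
import pytest

from charkit import simulate as sim


def random_additive_matrix(n, rng):
    """Additive distances from a random binary tree (independent oracle for
    neighbor-joining recovery tests)."""
    import skbio

    labels = [chr(ord("A") + i) for i in range(n)]
    nodes = [skbio.TreeNode(name=lab, length=float(rng.uniform(0.05, 1.0)))
             for lab in labels]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        child_j = nodes.pop(j)
        child_i = nodes.pop(i)
        parent = skbio.TreeNode(length=float(rng.uniform(0.05, 1.0)),
                                children=[child_i, child_j])
        nodes.append(parent)
    root = skbio.TreeNode(children=nodes)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = root.find(labels[i]).distance(
                root.find(labels[j])
            )
    return labels, d, root


@pytest.fixture
def acibel004():
    return sim.PRESETS["acibel004"]


@pytest.fixture
def acibel007():
    return sim.PRESETS["acibel007"]


@pytest.fixture
def rng():
    return np.random.default_rng(20240)
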