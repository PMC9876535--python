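import numpy as np
import pytest

from plinet.mst import Tree


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def star9():
    """Star on nine vertices, centre 0."""
    return Tree(9, tuple((0, i) for i in range(1, 9)))


@pytest.fixture
def path9():
    """Path on nine vertices, 0-1-2-...-8."""
    return Tree(9, tuple((i, i + 1) for i in range(8)))


def random_tree(n: int, rng: np.random.Generator) -> Tree:
    """Uniform random labeled tree via a random Pruefer sequence."""
    if n == 2:
        return Tree(2, ((0, 1),))
    prufer = rng.integers(0, n, size=n - 2)
    return tree_from_prufer(prufer, n)


def tree_from_prufer(prufer, n: int) -> Tree:
    """Decode a Pruefer sequence into the labeled tree it encodes."""
    degree = np.ones(n, dtype=int)
    for v in prufer:
        degree[v] += 1
    edges = []
    import heapq

    leaves = [v for v in range(n) if degree[v] == 1]
    heapq.heapify(leaves)
    for v in prufer:
        leaf = heapq.heappop(leaves)
        edges.append((leaf, int(v)))
        degree[v] -= 1
        if degree[v] == 1:
            heapq.heappush(leaves, int(v))
    u, w = leaves[0], leaves[1]
    edges.append((u, w))
    return Tree(n, tuple(edges))
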