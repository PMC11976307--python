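import numpy as np
import pytest

from cordytrace import build_locality_table_from_fixture, load_reference_fixture


@pytest.fixture(scope="session")
def reference_fixture():
    return load_reference_fixture()


@pytest.fixture(scope="session")
def reference_table(reference_fixture):
    return build_locality_table_from_fixture(reference_fixture)


def random_additive_tree(rng: np.random.Generator, n_leaves: int):
    """Random binary tree with positive branch lengths; independent oracle.

    Returns (labels, distance matrix of all-pairs path lengths) computed by
    explicit graph traversal, without any package tree code.
    """
    # node ids: leaves get labels; edges as adjacency with lengths
    adj: dict[int, dict[int, float]] = {0: {}, 1: {}}
    nxt = 2

    def add_edge(a, b, w):
        adj.setdefault(a, {})[b] = w
        adj.setdefault(b, {})[a] = w

    def drop_edge(a, b):
        del adj[a][b]
        del adj[b][a]

    add_edge(0, 1, float(rng.uniform(0.5, 2.0)))
    leaves = [0, 1]
    for _ in range(n_leaves - 2):
        edges = [(a, b) for a in adj for b in adj[a] if a < b]
        a, b = edges[rng.integers(0, len(edges))]
        w = adj[a][b]
        t = float(rng.uniform(0.2, 0.8))
        mid, leaf = nxt, nxt + 1
        nxt += 2
        drop_edge(a, b)
        add_edge(a, mid, w * t)
        add_edge(mid, b, w * (1 - t))
        add_edge(mid, leaf, float(rng.uniform(0.5, 2.0)))
        leaves.append(leaf)

    def path_len(s, g):
        stack = [(s, 0.0, -1)]
        while stack:
            node, dist, parent = stack.pop()
            if node == g:
                return dist
            for nbr, w in adj[node].items():
                if nbr != parent:
                    stack.append((nbr, dist + w, node))
        raise AssertionError("disconnected oracle tree")

    labels = tuple(f"T{k}" for k in range(len(leaves)))
    n = len(leaves)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = path_len(leaves[i], leaves[j])
    return labels, d
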