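"""Independent oracles used by the test suite.

These deliberately avoid the package's own code paths: topology enumeration
plus non-negative least squares stands against neighbor joining, and a naive
per-pair double loop stands against the vectorised p-distance.
"""

import itertools

import numpy as np


def random_tree_newick(n, rng):
    """Random binary topology with uniform branch lengths in [0.1, 1]."""
    nodes = [f"t{i}" for i in range(n)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        bl_a, bl_b = rng.uniform(0.1, 1.0, size=2)
        merged = f"({a}:{bl_a:.6f},{b}:{bl_b:.6f})"
        nodes = [x for k, x in enumerate(nodes) if k not in (i, j)] + [merged]
    return nodes[0] + ";"


def enumerate_topologies(labels):
    """Edge lists of every unrooted binary topology on the labels."""
    first = labels[:3]
    base_edges = [(l, "h0") for l in first]
    trees = [(base_edges, 1)]
    for leaf in labels[3:]:
        nxt = []
        for edges, h in trees:
            for k, (u, v) in enumerate(edges):
                w = f"h{h}"
                new_edges = (
                    edges[:k] + edges[k + 1:] + [(u, w), (w, v), (leaf, w)]
                )
                nxt.append((new_edges, h + 1))
        trees = nxt
    return [edges for edges, _ in trees]


def topology_splits(edges, labels):
    """Nontrivial splits (canonical frozensets) of an edge list."""
    import networkx as nx

    g = nx.Graph(edges)
    ref = sorted(labels)[0]
    out = set()
    for u, v in edges:
        h = g.copy()
        h.remove_edge(u, v)
        comp = nx.node_connected_component(h, u)
        side = frozenset(x for x in comp if x in labels)
        if ref in side:
            side = frozenset(set(labels) - side)
        if 2 <= len(side) <= len(labels) - 2:
            out.add(side)
    return out


def least_squares_sse(edges, labels, D):
    """Non-negative least-squares fit of branch lengths to distances."""
    import networkx as nx
    from scipy.optimize import nnls

    g = nx.Graph()
    for k, (u, v) in enumerate(edges):
        g.add_edge(u, v, idx=k)
    pairs = list(itertools.combinations(range(len(labels)), 2))
    A = np.zeros((len(pairs), len(edges)))
    b = np.zeros(len(pairs))
    for r, (i, j) in enumerate(pairs):
        path = nx.shortest_path(g, labels[i], labels[j])
        for u, v in zip(path, path[1:]):
            A[r, g[u][v]["idx"]] = 1.0
        b[r] = D[i, j]
    x, _ = nnls(A, b)
    return float(((A @ x - b) ** 2).sum())


def naive_p_distance(rows, deletion):
    """Per-pair double-loop p-distance, pairwise or complete deletion."""
    n = len(rows)
    cols = range(len(rows[0]))
    if deletion == "complete":
        cols = [c for c in cols if all(r[c] != "-" for r in rows)]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = [
                c for c in cols if rows[i][c] != "-" and rows[j][c] != "-"
            ]
            diff = sum(rows[i][c] != rows[j][c] for c in shared)
            out[i, j] = diff / len(shared) if shared else np.nan
    return out
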