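"""Shared fixtures and independent brute-force oracles.

The centrality oracles here deliberately avoid the package's algorithms:
betweenness is counted by exhaustive simple-path enumeration, closeness
from raw BFS distance sums, eigenvector centrality from a dense
symmetric eigensolver, degree from adjacency-matrix row sums.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
import pytest


def brute_degree(g: nx.Graph) -> dict:
    nodes = sorted(g.nodes)
    a = nx.to_numpy_array(g, nodelist=nodes)
    return dict(zip(nodes, a.sum(axis=1)))


def _all_shortest_paths(g: nx.Graph, s, t) -> list:
    """Every shortest s-t path, by exhaustive simple-path enumeration."""
    best: list = []
    best_len = None

    def dfs(node, path):
        nonlocal best, best_len
        if best_len is not None and len(path) - 1 > best_len:
            return
        if node == t:
            d = len(path) - 1
            if best_len is None or d < best_len:
                best, best_len = [list(path)], d
            elif d == best_len:
                best.append(list(path))
            return
        for w in g[node]:
            if w not in path:
                path.append(w)
                dfs(w, path)
                path.pop()

    dfs(s, [s])
    return best


def brute_betweenness(g: nx.Graph) -> dict:
    """Unnormalised betweenness, endpoints excluded, each pair once."""
    bc = {v: 0.0 for v in g}
    nodes = sorted(g.nodes)
    for s, t in itertools.combinations(nodes, 2):
        paths = _all_shortest_paths(g, s, t)
        if not paths:
            continue
        for p in paths:
            for v in p[1:-1]:
                bc[v] += 1.0 / len(paths)
    return bc


def brute_closeness(g: nx.Graph) -> dict:
    cc = {}
    for v in g:
        dist = nx.single_source_shortest_path_length(g, v)
        total = sum(dist.values())
        cc[v] = (len(dist) - 1) / total if total else 0.0
    return cc


def brute_eigenvector(g: nx.Graph) -> dict:
    """Principal eigenvector of the largest component, max-normalised."""
    comp = max(nx.connected_components(g), key=lambda c: (len(c), sorted(c)))
    nodes = sorted(comp)
    ec = {v: 0.0 for v in g}
    if len(nodes) == 1:
        ec[nodes[0]] = 1.0
        return ec
    a = nx.to_numpy_array(g.subgraph(nodes), nodelist=nodes)
    w, vecs = np.linalg.eigh(a)
    principal = np.abs(vecs[:, np.argmax(w)])
    principal = principal / principal.max()
    ec.update(dict(zip(nodes, principal)))
    return ec


def random_graph(rng: np.random.Generator, n_max: int = 8) -> nx.Graph:
    n = int(rng.integers(2, n_max + 1))
    p = float(rng.uniform(0.2, 0.9))
    g = nx.Graph()
    g.add_nodes_from(f"N{i}" for i in range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                g.add_edge(f"N{i}", f"N{j}")
    return g


@pytest.fixture(scope="session")
def small_graph_suite() -> list:
    """All connected graphs on <= 6 nodes (graph atlas) plus 200 random
    graphs on <= 8 nodes, relabelled to string names."""
    suite = []
    for g in nx.graph_atlas_g():
        if 1 <= g.number_of_nodes() <= 6 and nx.is_connected(g):
            suite.append(nx.relabel_nodes(g, {v: f"N{v}" for v in g.nodes}))
    rng = np.random.default_rng(20240917)
    suite.extend(random_graph(rng) for _ in range(200))
    return suite
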