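"""Independent brute-force oracles for path metrics on small graphs.

Everything here works by exhaustive enumeration of simple paths, with no
shared code with the package's Dijkstra/Yen/Brandes routes, so agreement is
a meaningful cross-check.  Intended for graphs of at most ~8 nodes.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np

TIE_TOL = 1e-12


def simple_paths_info(g: nx.DiGraph, source, target):
    """All simple paths source->target as (path, length, hops) tuples.

    Lengths are accumulated left-to-right along the path, matching the
    accumulation order of Dijkstra-style algorithms.
    """
    out = []
    for path in nx.all_simple_paths(g, source, target):
        length = 0.0
        for a, b in zip(path, path[1:]):
            length += g[a][b]["weight"]
        out.append((tuple(path), length, len(path) - 1))
    return out


def oracle_shortest(g, source, target):
    """Min-length path with (length, hops, lexicographic) tie-breaking."""
    if source == target:
        return (source,), 0.0, 0
    infos = simple_paths_info(g, source, target)
    if not infos:
        return None
    best_len = min(i[1] for i in infos)
    ties = [i for i in infos if i[1] <= best_len + TIE_TOL]
    ties.sort(key=lambda i: (i[2], i[0]))
    path, _, hops = ties[0]
    return path, best_len, hops


def oracle_k_shortest(g, source, target, k):
    infos = simple_paths_info(g, source, target)
    infos.sort(key=lambda i: (i[1], i[2], i[0]))
    return infos[:k]


def oracle_distance_matrix(g):
    nodes = sorted(g.nodes)
    out = {}
    for s, t in itertools.product(nodes, nodes):
        if s == t:
            out[(s, t)] = 0.0
        else:
            infos = simple_paths_info(g, s, t)
            out[(s, t)] = min((i[1] for i in infos), default=np.inf)
    return out


def oracle_dos(g, source, target):
    """Minimum hop count ignoring weights."""
    if source == target:
        return 0
    infos = simple_paths_info(g, source, target)
    return min((i[2] for i in infos), default=np.inf)


def oracle_weighted_dos(g, source, target):
    """Hops of the minimum-weighted-length path, min hops among ties."""
    if source == target:
        return 0
    infos = simple_paths_info(g, source, target)
    if not infos:
        return np.inf
    best_len = min(i[1] for i in infos)
    return min(i[2] for i in infos if i[1] <= best_len + TIE_TOL)


def oracle_betweenness(g):
    """Ordered-pair-normalized betweenness by counting co-minimal paths."""
    nodes = sorted(g.nodes)
    n = len(nodes)
    raw = {v: 0.0 for v in nodes}
    for s, t in itertools.permutations(nodes, 2):
        infos = simple_paths_info(g, s, t)
        if not infos:
            continue
        best = min(i[1] for i in infos)
        minimal = [i[0] for i in infos if i[1] <= best + TIE_TOL]
        sigma = len(minimal)
        for v in nodes:
            if v in (s, t):
                continue
            sigma_v = sum(1 for p in minimal if v in p)
            raw[v] += sigma_v / sigma
    if n > 2:
        for v in raw:
            raw[v] /= (n - 1) * (n - 2)
    return raw


def random_density_graph(seed, max_nodes=8, p=0.45, low=0.05, high=1.0):
    """A random directed density matrix for oracle comparisons."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(3, max_nodes + 1))
    dens = rng.uniform(low, high, size=(n, n))
    mask = rng.random((n, n)) < p
    np.fill_diagonal(mask, False)
    import pandas as pd

    labels = [f"n{i}" for i in range(n)]
    return pd.DataFrame(np.where(mask, dens, 0.0), index=labels, columns=labels)
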