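"""Node-, path-, and network-level metrics on tracer connectomes.

Projection density is a *conductance*-like quantity, so traversal cost is its
inverse: edge weight w(i, j) = 1 / d(i, j), optionally padded by a synapse
factor s modeling the cost of crossing a synapse (additive, w = 1/d + s, or
multiplicative, w = s/d).  On top of that weight graph the module provides
Dijkstra shortest paths with deterministic tie-breaking, k shortest loopless
paths, Brandes betweenness centrality, and the binary-network measures:
thresholded binarization, degree of separation (DOS, minimum hop count) and
weighted DOS (hop count of the minimum-weighted-distance path).

Most operations accept either a bilateral matrix (mirror-expanded on the
fly), a square pandas DataFrame of densities, or a directed graph whose
edges carry a ``density`` attribute.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .build import BilateralMatrix, expand_bilateral
from .config import MIDLINE_UM, MIRROR_AXIS, PATH_TIE_TOL
from .ontology import StructureTree, centroid_distance


# ---------------------------------------------------------------------------
# Representation plumbing
# ---------------------------------------------------------------------------


def to_density_frame(obj) -> pd.DataFrame:
    """Coerce any supported network representation to a square density frame."""
    if isinstance(obj, BilateralMatrix):
        obj = expand_bilateral(obj)
    if isinstance(obj, nx.DiGraph):
        nodes = sorted(obj.nodes)
        return nx.to_pandas_adjacency(obj, nodelist=nodes, weight="density")
    if isinstance(obj, pd.DataFrame):
        if obj.shape[0] != obj.shape[1]:
            raise ValueError(f"expected a square matrix, got shape {obj.shape}")
        return obj
    arr = np.asarray(obj, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {arr.shape}")
    labels = [str(i) for i in range(arr.shape[0])]
    return pd.DataFrame(arr, index=labels, columns=labels)


# ---------------------------------------------------------------------------
# Degrees and ratios
# ---------------------------------------------------------------------------


def degrees(m, include_diagonal: bool = True) -> pd.DataFrame:
    """Weighted in-/out-degree per node.

    For a bilateral matrix, out-degree of a source node is its full row sum
    (both hemisphere blocks) and in-degree of a node sums both column blocks
    mapping to it; nodes without a measured row have undefined (NaN)
    out-degree.  For a square matrix, plain row/column sums.
    """
    if isinstance(m, BilateralMatrix):
        vals = m.values.copy()
        if not include_diagonal:
            for i, src in enumerate(m.source_nodes):
                vals[i, m.nodes.index(src)] = 0.0
        n = m.n
        out = pd.Series(np.nan, index=list(m.nodes), dtype=float)
        out.loc[list(m.source_nodes)] = vals.sum(axis=1)
        incol = vals[:, :n].sum(axis=0) + vals[:, n:].sum(axis=0)
        return pd.DataFrame({"in_degree": pd.Series(incol, index=list(m.nodes)), "out_degree": out})
    df = to_density_frame(m)
    vals = df.to_numpy(dtype=float).copy()
    if not include_diagonal:
        np.fill_diagonal(vals, 0.0)
    return pd.DataFrame(
        {"in_degree": vals.sum(axis=0), "out_degree": vals.sum(axis=1)},
        index=df.index,
    )


def node_ratios(m: BilateralMatrix, include_diagonal: bool = True) -> pd.DataFrame:
    """Convergence (in/out) and hemisphere (contra-out/total-out) ratios.

    Zero denominators yield NaN (undefined), never a division fault.
    """
    deg = degrees(m, include_diagonal=include_diagonal)
    with np.errstate(divide="ignore", invalid="ignore"):
        conv = deg["in_degree"] / deg["out_degree"]
    conv[deg["out_degree"] == 0] = np.nan
    vals = m.values.copy()
    if not include_diagonal:
        for i, src in enumerate(m.source_nodes):
            vals[i, m.nodes.index(src)] = 0.0
    total = vals.sum(axis=1)
    contra = vals[:, m.n :].sum(axis=1)
    hemi = pd.Series(np.nan, index=list(m.nodes), dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(total > 0, contra / total, np.nan)
    hemi.loc[list(m.source_nodes)] = ratio
    return pd.DataFrame({"convergence_ratio": conv, "hemisphere_ratio": hemi})


# ---------------------------------------------------------------------------
# Weight graph
# ---------------------------------------------------------------------------


def edge_weight_graph(m, synapse_factor: float = 0.0, mode: str = "additive") -> nx.DiGraph:
    """Directed graph with traversal weights w = 1/d + s or w = s/d.

    Zero-density pairs produce no edge (absence, not infinite weight) and
    self-loops are dropped; every emitted weight is positive and finite.
    """
    if synapse_factor < 0:
        raise ValueError("synapse factor must be >= 0")
    if mode not in ("additive", "multiplicative"):
        raise ValueError(f"unknown synapse-factor mode {mode!r}")
    if mode == "multiplicative" and synapse_factor <= 0:
        raise ValueError("multiplicative mode requires synapse factor > 0")
    df = to_density_frame(m)
    g = nx.DiGraph()
    g.graph["synapse_factor"] = synapse_factor
    g.graph["synapse_mode"] = mode
    g.add_nodes_from(df.index)
    vals = df.to_numpy(dtype=float)
    n = vals.shape[0]
    labels = list(df.index)
    for i in range(n):
        for j in range(n):
            d = vals[i, j]
            if i == j or d <= 0:
                continue
            w = 1.0 / d + synapse_factor if mode == "additive" else synapse_factor / d
            g.add_edge(labels[i], labels[j], weight=w, density=float(d))
    return g


# ---------------------------------------------------------------------------
# Shortest paths (deterministic tie-breaking)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PathResult:
    """A path, its summed edge-weight length, and its hop (synapse) count."""

    nodes: tuple
    total_length: float
    hops: int


def _check_nodes(g: nx.DiGraph, *nodes) -> None:
    for v in nodes:
        if v not in g:
            raise KeyError(f"unknown node {v!r}")


def _single_source(g: nx.DiGraph, source) -> dict:
    """Dijkstra returning per-target (length, hops) with min-hop tie-break."""
    best: dict = {}
    heap = [(0.0, 0, source)]
    while heap:
        length, hops, v = heapq.heappop(heap)
        if v in best:
            continue
        best[v] = (length, hops)
        for u, attrs in g[v].items():
            if u not in best:
                heapq.heappush(heap, (length + attrs["weight"], hops + 1, u))
    return best


def shortest_path(g: nx.DiGraph, source, target) -> Optional[PathResult]:
    """Minimum-total-length path, or None if the target is unreachable.

    Ties on length (within the package tie tolerance) are broken by fewer
    hops, then by lexicographic node sequence, making the result
    deterministic.
    """
    _check_nodes(g, source, target)
    if source == target:
        return PathResult((source,), 0.0, 0)
    done = set()
    heap = [(0.0, 0, (source,))]
    while heap:
        length, hops, path = heapq.heappop(heap)
        v = path[-1]
        if v in done:
            continue
        done.add(v)
        if v == target:
            return PathResult(path, length, hops)
        for u, attrs in g[v].items():
            if u not in done:
                heapq.heappush(heap, (length + attrs["weight"], hops + 1, path + (u,)))
    return None


def all_pairs_weighted_distance(g: nx.DiGraph) -> pd.DataFrame:
    """Matrix of minimal summed edge weights; unreachable pairs are inf."""
    nodes = sorted(g.nodes)
    out = pd.DataFrame(np.inf, index=nodes, columns=nodes, dtype=float)
    for s in nodes:
        for t, (length, _) in _single_source(g, s).items():
            out.loc[s, t] = length
    return out


def k_shortest_paths(g: nx.DiGraph, source, target, k: int = 1) -> list[PathResult]:
    """The k shortest simple (loopless) paths, deterministically ordered.

    Uses Yen's algorithm, then sorts by (length, hops, node sequence) so
    equal-length paths appear in a reproducible order.  Fewer than k results
    are returned when fewer simple paths exist.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    _check_nodes(g, source, target)
    if source == target:
        return [PathResult((source,), 0.0, 0)]
    results: list[PathResult] = []
    try:
        gen = nx.shortest_simple_paths(g, source, target, weight="weight")
        for path in gen:
            length = 0.0
            for a, b in zip(path, path[1:]):
                length += g[a][b]["weight"]
            results.append(PathResult(tuple(path), length, len(path) - 1))
            # Keep collecting while paths tie with the k-th best length.
            if len(results) >= k and length > results[k - 1].total_length + PATH_TIE_TOL:
                break
    except nx.NetworkXNoPath:
        return []
    results.sort(key=lambda p: (p.total_length, p.hops, p.nodes))
    return results[:k]


def betweenness(g: nx.DiGraph) -> pd.Series:
    """Brandes betweenness centrality, normalized over ordered pairs.

    Each node accrues the fraction of equally-minimal weighted shortest paths
    passing through it, summed over ordered (source, target) pairs and
    divided by (n-1)(n-2), so values lie in [0, 1].
    """
    bc = nx.betweenness_centrality(g, normalized=True, weight="weight")
    return pd.Series(bc).sort_index()


# ---------------------------------------------------------------------------
# Binary network analysis
# ---------------------------------------------------------------------------


def binarize(m, threshold: float, strict: bool = True):
    """Threshold projection densities to a 0/1 network.

    An edge survives iff its density exceeds the threshold (strictly by
    default; ``strict=False`` uses >=).  The diagonal (self-connections) is
    forced to 0 so binary path measures never use self-loops.  Bilateral
    matrices come back as bilateral matrices, everything else as a square
    frame.
    """
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must lie in [0, 1]")
    if isinstance(m, BilateralMatrix):
        cmp = m.values > threshold if strict else m.values >= threshold
        vals = cmp.astype(float)
        for i, src in enumerate(m.source_nodes):
            vals[i, m.nodes.index(src)] = 0.0
        return m.copy_with(vals, threshold=threshold, binary=True)
    df = to_density_frame(m)
    cmp = df.to_numpy(dtype=float) > threshold if strict else df.to_numpy(dtype=float) >= threshold
    vals = cmp.astype(float)
    np.fill_diagonal(vals, 0.0)
    return pd.DataFrame(vals, index=df.index, columns=df.columns)


def dos_matrix(binary) -> pd.DataFrame:
    """Degree of separation: minimum hop count per ordered pair.

    Breadth-first search on the binarized support; diagonal 0, unreachable
    pairs inf.  On a unit-weight graph this equals the weighted distance.
    """
    df = to_density_frame(binary)
    g = nx.from_pandas_adjacency(df, create_using=nx.DiGraph)
    g.remove_edges_from(nx.selfloop_edges(g))
    nodes = sorted(df.index)
    out = pd.DataFrame(np.inf, index=nodes, columns=nodes, dtype=float)
    for s in nodes:
        for t, hops in nx.single_source_shortest_path_length(g, s).items():
            out.loc[s, t] = hops
    return out


def weighted_dos_matrix(g: nx.DiGraph) -> pd.DataFrame:
    """Hop count of the minimum-weighted-distance path per ordered pair.

    Among equally short weighted paths the minimum hop count is reported.
    Diagonal 0; unreachable pairs inf.
    """
    nodes = sorted(g.nodes)
    out = pd.DataFrame(np.inf, index=nodes, columns=nodes, dtype=float)
    for s in nodes:
        for t, (_, hops) in _single_source(g, s).items():
            out.loc[s, t] = hops
    return out


def average_finite(matrix: pd.DataFrame, exclude_diagonal: bool = True) -> tuple[float, int]:
    """Mean over finite entries (and their count), diagonal excluded by default."""
    vals = matrix.to_numpy(dtype=float).copy()
    if exclude_diagonal:
        np.fill_diagonal(vals, np.inf)
    finite = vals[np.isfinite(vals)]
    if finite.size == 0:
        return float("nan"), 0
    return float(finite.mean()), int(finite.size)


# ---------------------------------------------------------------------------
# Spatially weighted and comparative densities
# ---------------------------------------------------------------------------


def weighted_density(
    m: BilateralMatrix,
    tree: StructureTree,
    midline: float = MIDLINE_UM,
    axis: int = MIRROR_AXIS,
) -> BilateralMatrix:
    """Density times inter-centroid Euclidean distance (micrometer scale).

    Highlights strong long-range projections; contralateral columns use the
    mirrored-centroid distance.
    """
    n = m.n
    dist = np.zeros_like(m.values)
    for i, src in enumerate(m.source_nodes):
        for j, tgt in enumerate(m.nodes):
            dist[i, j] = centroid_distance(src, tgt, True, tree, midline=midline, axis=axis)
            dist[i, n + j] = centroid_distance(src, tgt, False, tree, midline=midline, axis=axis)
    return m.copy_with(m.values * dist, weighted_by_distance=True)


def relative_density(a, b):
    """Element-wise (a - b) / (a + b) contrast in [-1, 1]; 0/0 maps to 0."""
    av = a.values if isinstance(a, BilateralMatrix) else np.asarray(a, dtype=float)
    bv = b.values if isinstance(b, BilateralMatrix) else np.asarray(b, dtype=float)
    if av.shape != bv.shape:
        raise ValueError(f"shape mismatch: {av.shape} vs {bv.shape}")
    num = av - bv
    den = av + bv
    out = np.zeros_like(num, dtype=float)
    np.divide(num, den, out=out, where=den != 0)
    if isinstance(a, BilateralMatrix):
        return a.copy_with(out, relative_to=True)
    if isinstance(a, pd.DataFrame):
        return pd.DataFrame(out, index=a.index, columns=a.columns)
    return out


# ---------------------------------------------------------------------------
# Whole-network summary numbers
# ---------------------------------------------------------------------------


def ipsi_mass_fraction(m: BilateralMatrix, include_diagonal: bool = True) -> float:
    """Fraction of total projection mass confined to the ipsilateral block."""
    vals = m.values.copy()
    if not include_diagonal:
        for i, src in enumerate(m.source_nodes):
            vals[i, m.nodes.index(src)] = 0.0
    total = vals.sum()
    return float(vals[:, : m.n].sum() / total) if total > 0 else float("nan")


def edge_density(m: BilateralMatrix, include_diagonal: bool = False) -> float:
    """Fraction of possible source->target connections with nonzero density."""
    vals = m.values.copy()
    possible = vals.size
    if not include_diagonal:
        for i, src in enumerate(m.source_nodes):
            vals[i, m.nodes.index(src)] = 0.0
        possible -= len(m.source_nodes)
    return float((vals > 0).sum() / possible) if possible else float("nan")
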