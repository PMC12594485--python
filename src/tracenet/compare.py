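"""Group comparison, macro-region condensation, and GEXF export/import.

Comparative analyses (e.g., male vs. female networks) first *align* two
matrices to their common source nodes, then contrast them cell-wise with
relative density; a *comparative map* dual-encodes a base network with the
signed dominance layer wherever both groups contributed data.  *Macromaps*
condense a matrix by averaging entries within user-defined macro areas
(e.g., isocortex, thalamus).  Networks are exchanged with visualization
tools through GEXF (Graph Exchange XML Format), written deterministically so
identical graphs produce byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import networkx as nx
import numpy as np
import pandas as pd
from lxml import etree

from .build import BilateralMatrix, expand_bilateral
from .config import logger
from .analysis import relative_density
from .ontology import StructureTree


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------


def align_networks(
    a: BilateralMatrix, b: BilateralMatrix
) -> tuple[BilateralMatrix, BilateralMatrix, list[int], list[int]]:
    """Restrict two matrices to their common source nodes (rows and columns).

    Returns the two restricted matrices plus the source nodes dropped from
    each.  Both inputs must share the same node-list universe.
    """
    if a.nodes != b.nodes:
        raise ValueError("matrices are not built over the same node list")
    common = [nid for nid in a.nodes if nid in set(a.source_nodes) & set(b.source_nodes)]
    if not common:
        raise ValueError("no common source nodes between the two networks")
    dropped_a = [s for s in a.source_nodes if s not in common]
    dropped_b = [s for s in b.source_nodes if s not in common]

    def restrict(m: BilateralMatrix) -> BilateralMatrix:
        rows = [m.source_nodes.index(s) for s in common]
        cols = [m.nodes.index(t) for t in common]
        n = m.n
        vals = np.hstack(
            [m.values[np.ix_(rows, cols)], m.values[np.ix_(rows, [c + n for c in cols])]]
        )
        return BilateralMatrix(
            values=vals,
            source_nodes=tuple(common),
            nodes=tuple(common),
            measure=m.measure,
            params={**m.params, "aligned": True},
        )

    return restrict(a), restrict(b), dropped_a, dropped_b


# ---------------------------------------------------------------------------
# Macro-region condensation
# ---------------------------------------------------------------------------


def _block_mean(block: np.ndarray, include_zeros: bool) -> float:
    if include_zeros:
        return float(block.mean())
    nz = block[block != 0]
    return float(nz.mean()) if nz.size else 0.0


def macromap(m, grouping: dict, include_zeros: bool = True) -> pd.DataFrame:
    """Condense a matrix by averaging entries within macro-area blocks.

    For a bilateral matrix ``grouping`` maps node ids to macro labels and the
    ipsi/contra blocks are condensed separately (columns prefixed ``L:`` /
    ``R:``).  For a square frame it maps the frame's axis labels.  Every node
    must be grouped; zero cells are included in the mean by default.
    """
    if isinstance(m, BilateralMatrix):
        for nid in set(m.nodes) | set(m.source_nodes):
            if nid not in grouping:
                raise KeyError(f"node {nid} has no macro-area label")
        row_groups = sorted({grouping[s] for s in m.source_nodes})
        col_groups = sorted({grouping[t] for t in m.nodes})
        out = pd.DataFrame(
            0.0,
            index=row_groups,
            columns=[f"L:{g}" for g in col_groups] + [f"R:{g}" for g in col_groups],
        )
        n = m.n
        for gr in row_groups:
            rows = [i for i, s in enumerate(m.source_nodes) if grouping[s] == gr]
            for gc in col_groups:
                cols = [j for j, t in enumerate(m.nodes) if grouping[t] == gc]
                out.loc[gr, f"L:{gc}"] = _block_mean(m.values[np.ix_(rows, cols)], include_zeros)
                out.loc[gr, f"R:{gc}"] = _block_mean(
                    m.values[np.ix_(rows, [n + c for c in cols])], include_zeros
                )
        return out
    df = m if isinstance(m, pd.DataFrame) else pd.DataFrame(np.asarray(m, dtype=float))
    for lab in list(df.index) + list(df.columns):
        if lab not in grouping:
            raise KeyError(f"node {lab!r} has no macro-area label")
    row_groups = sorted({grouping[r] for r in df.index})
    col_groups = sorted({grouping[c] for c in df.columns})
    out = pd.DataFrame(0.0, index=row_groups, columns=col_groups)
    vals = df.to_numpy(dtype=float)
    for gr in row_groups:
        rows = [i for i, r in enumerate(df.index) if grouping[r] == gr]
        for gc in col_groups:
            cols = [j for j, c in enumerate(df.columns) if grouping[c] == gc]
            out.loc[gr, gc] = _block_mean(vals[np.ix_(rows, cols)], include_zeros)
    return out


def grouping_from_tree(
    nodes, tree: StructureTree, depth: int = 1
) -> dict[int, str]:
    """Default macro grouping: the ontology ancestor at a fixed depth."""
    return {nid: tree.get(tree.ancestor_at_depth(nid, depth)).acronym for nid in nodes}


def load_grouping(path: str | Path) -> dict[int, str]:
    """Read a ``node_id,label`` CSV override file."""
    out = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("node_id"):
            continue
        nid, label = line.split(",", 1)
        out[int(nid)] = label.strip()
    return out


# ---------------------------------------------------------------------------
# GEXF export / import
# ---------------------------------------------------------------------------

GEXF_NS = "http://gexf.net/1.3"

_NODE_ATTRS = (
    ("acronym", "string"),
    ("hemisphere", "string"),
    ("macro", "string"),
    ("x", "double"),
    ("y", "double"),
    ("z", "double"),
)


def export_gexf(
    g,
    path: str | Path,
    tree: Optional[StructureTree] = None,
    grouping: Optional[dict] = None,
) -> None:
    """Write a directed weighted graph as GEXF 1.3.

    Edge weight carries the projection *density* (not the inverse traversal
    weight), matching the convention that edge thickness shows connection
    strength.  Elements are emitted in sorted node/edge order, so exporting
    the same graph twice yields byte-identical files.
    """
    if isinstance(g, BilateralMatrix):
        g = expand_bilateral(g)
    root = etree.Element(f"{{{GEXF_NS}}}gexf", nsmap={None: GEXF_NS})
    root.set("version", "1.3")
    graph = etree.SubElement(root, f"{{{GEXF_NS}}}graph")
    graph.set("defaultedgetype", "directed")
    attrs_el = etree.SubElement(graph, f"{{{GEXF_NS}}}attributes")
    attrs_el.set("class", "node")
    for i, (title, typ) in enumerate(_NODE_ATTRS):
        a = etree.SubElement(attrs_el, f"{{{GEXF_NS}}}attribute")
        a.set("id", str(i))
        a.set("title", title)
        a.set("type", typ)
    attr_index = {title: str(i) for i, (title, _) in enumerate(_NODE_ATTRS)}

    nodes_el = etree.SubElement(graph, f"{{{GEXF_NS}}}nodes")
    for nid in sorted(g.nodes, key=str):
        data = g.nodes[nid]
        el = etree.SubElement(nodes_el, f"{{{GEXF_NS}}}node")
        el.set("id", str(nid))
        sid = data.get("structure_id")
        acronym = None
        centroid = None
        if tree is not None and sid is not None and sid in tree:
            rec = tree.get(sid)
            acronym = rec.acronym
            centroid = rec.centroid
        label = f"{data['hemisphere']}:{acronym}" if acronym and "hemisphere" in data else str(nid)
        el.set("label", label)
        values = {
            "acronym": acronym,
            "hemisphere": data.get("hemisphere"),
            "macro": grouping.get(sid) if grouping and sid is not None else None,
        }
        if centroid is not None:
            values.update(zip(("x", "y", "z"), (repr(float(c)) for c in centroid)))
        av = etree.SubElement(el, f"{{{GEXF_NS}}}attvalues")
        for title, val in values.items():
            if val is None:
                continue
            v = etree.SubElement(av, f"{{{GEXF_NS}}}attvalue")
            v.set("for", attr_index[title])
            v.set("value", str(val))

    edges_el = etree.SubElement(graph, f"{{{GEXF_NS}}}edges")
    for idx, (u, v) in enumerate(sorted(g.edges, key=lambda e: (str(e[0]), str(e[1])))):
        attrs = g.edges[u, v]
        weight = attrs.get("density", attrs.get("weight", 1.0))
        el = etree.SubElement(edges_el, f"{{{GEXF_NS}}}edge")
        el.set("id", str(idx))
        el.set("source", str(u))
        el.set("target", str(v))
        el.set("weight", repr(float(weight)))

    Path(path).write_bytes(
        etree.tostring(root, xml_declaration=True, encoding="UTF-8", pretty_print=True)
    )


def import_gexf(path: str | Path) -> nx.DiGraph:
    """Read a GEXF file back into a directed graph.

    Inverse of :func:`export_gexf` under the documented attribute mapping;
    undirected files are rejected, and edges without a weight default to 1.0
    with a warning.
    """
    try:
        doc = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise ValueError(f"malformed GEXF file {path}: {exc}") from exc
    graph_el = doc.find("{*}graph")
    if graph_el is None:
        raise ValueError(f"{path}: no <graph> element")
    if graph_el.get("defaultedgetype", "undirected") != "directed":
        raise ValueError(f"{path}: only directed GEXF graphs are supported")
    attr_titles = {}
    for attrs_el in graph_el.findall("{*}attributes"):
        if attrs_el.get("class") == "node":
            for a in attrs_el.findall("{*}attribute"):
                attr_titles[a.get("id")] = (a.get("title"), a.get("type"))
    g = nx.DiGraph()
    for node_el in graph_el.findall("{*}nodes/{*}node"):
        nid = node_el.get("id")
        data = {"label": node_el.get("label", nid)}
        for v in node_el.findall("{*}attvalues/{*}attvalue"):
            title, typ = attr_titles.get(v.get("for"), (v.get("for"), "string"))
            raw = v.get("value")
            data[title] = float(raw) if typ == "double" else raw
        g.add_node(nid, **data)
    missing_weight = 0
    for edge_el in graph_el.findall("{*}edges/{*}edge"):
        w = edge_el.get("weight")
        if w is None:
            w = 1.0
            missing_weight += 1
        g.add_edge(edge_el.get("source"), edge_el.get("target"), density=float(w))
    if missing_weight:
        logger.warning("%s: %d edges without weight defaulted to 1.0", path, missing_weight)
    return g


# ---------------------------------------------------------------------------
# Comparative (dual-encoded) maps
# ---------------------------------------------------------------------------


@dataclass
class ComparativeMap:
    """A base network plus a signed group-dominance layer.

    ``dominance`` holds the relative density (group a vs. group b) wherever
    both groups contributed a row for the cell's source node and NaN where
    they did not; ``no_group_data`` flags those cells, whose ``base`` value
    (the combined network) is shown instead.
    """

    base: np.ndarray
    dominance: np.ndarray
    no_group_data: np.ndarray  # boolean mask
    source_nodes: tuple[int, ...]
    nodes: tuple[int, ...]


def comparative_map(
    a: BilateralMatrix, b: BilateralMatrix, base: BilateralMatrix
) -> ComparativeMap:
    """Overlay the a-vs-b dominance contrast on a base network.

    All three matrices must share the node-list universe, and the base must
    cover every source present in either group.
    """
    if not (a.nodes == b.nodes == base.nodes):
        raise ValueError("comparative_map requires matrices over the same node list")
    missing = (set(a.source_nodes) | set(b.source_nodes)) - set(base.source_nodes)
    if missing:
        raise ValueError(f"base network lacks source nodes {sorted(missing)}")
    dominance = np.full_like(base.values, np.nan)
    flags = np.ones(base.values.shape, dtype=bool)
    both = set(a.source_nodes) & set(b.source_nodes)
    for i, src in enumerate(base.source_nodes):
        if src in both:
            dominance[i] = relative_density(a.row(src), b.row(src))
            flags[i] = False
    return ComparativeMap(
        base=base.values.copy(),
        dominance=dominance,
        no_group_data=flags,
        source_nodes=base.source_nodes,
        nodes=base.nodes,
    )


def save_comparative(cm: ComparativeMap, prefix: str | Path) -> None:
    """Write a comparative map as base/dominance/flag CSV triplet."""
    prefix = Path(prefix)
    acr = [str(n) for n in cm.nodes]
    cols = [f"L:{x}" for x in acr] + [f"R:{x}" for x in acr]
    idx = [str(n) for n in cm.source_nodes]
    pd.DataFrame(cm.base, index=idx, columns=cols).to_csv(f"{prefix}_base.csv")
    pd.DataFrame(cm.dominance, index=idx, columns=cols).to_csv(f"{prefix}_dominance.csv")
    pd.DataFrame(cm.no_group_data.astype(int), index=idx, columns=cols).to_csv(
        f"{prefix}_flags.csv"
    )
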