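"""Compile normalized experiments into bilateral connectivity matrices.

The central object is the N x 2N *bilateral matrix*: rows are injected source
nodes, the first N columns are ipsilateral targets and the last N columns
contralateral targets, all expressed in the injection-relative frame.  A
whole-brain 2N x 2N directed graph is obtained by mirror expansion, assuming
left/right homotopy (the unmeasured hemisphere's rows are the mirror image of
the measured ones) — every bilateral path statistic downstream inherits that
assumption.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .config import CONTRA, IPSI, MEASURES
from .experiments import Database, NormalizedExperiment, filter_experiments
from .ontology import NodeList, StructureTree


@dataclass
class BilateralMatrix:
    """S x 2N matrix of projection measures, rows = injected source nodes."""

    values: np.ndarray  # shape (S, 2N), entries in [0, 1]
    source_nodes: tuple[int, ...]  # ordered subset of the node list
    nodes: tuple[int, ...]  # the full node-list order defining columns
    measure: str = "density"
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.source_nodes = tuple(self.source_nodes)
        self.nodes = tuple(self.nodes)
        S, W = self.values.shape
        if S != len(self.source_nodes) or W != 2 * len(self.nodes):
            raise ValueError(
                f"shape {self.values.shape} inconsistent with "
                f"{len(self.source_nodes)} sources x 2*{len(self.nodes)} nodes"
            )

    @property
    def n(self) -> int:
        return len(self.nodes)

    @property
    def ipsi(self) -> np.ndarray:
        return self.values[:, : self.n]

    @property
    def contra(self) -> np.ndarray:
        return self.values[:, self.n :]

    def row(self, node_id: int) -> np.ndarray:
        return self.values[self.source_nodes.index(node_id)]

    def copy_with(self, values: np.ndarray, **params) -> "BilateralMatrix":
        return BilateralMatrix(
            values=values,
            source_nodes=self.source_nodes,
            nodes=self.nodes,
            measure=self.measure,
            params={**self.params, **params},
        )


def _experiment_row(ne: NormalizedExperiment, nodes: NodeList, measure: str) -> Optional[np.ndarray]:
    vmap = ne.values.get(measure)
    if vmap is None:
        return None
    n = len(nodes)
    row = np.zeros(2 * n)
    for (node, srel), v in vmap.items():
        j = nodes.index(node) + (0 if srel == IPSI else n)
        row[j] = v
    return row


def _as_experiments(db) -> list[NormalizedExperiment]:
    return db.experiments if isinstance(db, Database) else list(db)


def load_map(
    db,
    nodes: NodeList,
    measure: str = "density",
    subset: Optional[Iterable[int]] = None,
) -> BilateralMatrix:
    """Build the bilateral matrix from accepted experiments.

    Experiments sharing an injection node are element-wise averaged into one
    row; nodes never used as injection sites contribute no row (source-based
    parcellation).  ``subset`` optionally restricts to specific experiment
    ids.
    """
    exps = _as_experiments(db)
    if subset is not None:
        wanted = set(subset)
        exps = [ne for ne in exps if ne.experiment_id in wanted]
    rows: dict[int, list[np.ndarray]] = {}
    for ne in exps:
        row = _experiment_row(ne, nodes, measure)
        if row is not None:
            rows.setdefault(ne.injection_node, []).append(row)
    if not rows:
        raise ValueError("no-experiments")
    sources = tuple(nid for nid in nodes if nid in rows)
    values = np.vstack([np.mean(rows[nid], axis=0) for nid in sources])
    return BilateralMatrix(
        values=values, source_nodes=sources, nodes=tuple(nodes), measure=measure
    )


def group_experiments(
    exps: Sequence[NormalizedExperiment], nodes: NodeList, measure: str = "density"
) -> np.ndarray:
    """Element-wise mean row over a set of experiments (any injection nodes)."""
    rows = [r for ne in exps if (r := _experiment_row(ne, nodes, measure)) is not None]
    if not rows:
        raise ValueError("no-experiments")
    return np.mean(rows, axis=0)


_GRID_KEYS = {"sex", "strain", "transgenic_line", "injection_volume_range", "measure", "threshold"}


def generate_maps(
    db, nodes: NodeList, param_grid: dict[str, Sequence]
) -> list[tuple[dict, Optional[BilateralMatrix]]]:
    """Batch-build one matrix per point of the Cartesian parameter grid.

    Grid keys are the metadata filters plus ``measure`` and ``threshold``
    (entries strictly below the threshold are zeroed).  Grid points matching
    zero experiments yield ``(params, None)`` rather than raising.
    """
    unknown = set(param_grid) - _GRID_KEYS
    if unknown:
        raise ValueError(f"unknown grid parameters: {sorted(unknown)}")
    exps = _as_experiments(db)
    out = []
    keys = list(param_grid)
    for combo in itertools.product(*(param_grid[k] for k in keys)):
        params = dict(zip(keys, combo))
        measure = params.get("measure", "density")
        threshold = params.get("threshold")
        criteria = {
            k: v for k, v in params.items() if k not in ("measure", "threshold")
        }
        selected = filter_experiments(exps, **criteria)
        try:
            m = load_map(selected, nodes, measure=measure)
        except ValueError:
            out.append((params, None))
            continue
        if threshold is not None:
            vals = np.where(m.values >= threshold, m.values, 0.0)
            m = m.copy_with(vals, threshold=threshold)
        m.params.update(params)
        out.append((params, m))
    return out


def hemisphere_normalize(m: BilateralMatrix) -> BilateralMatrix:
    """Rescale each row's ipsi and contra blocks separately to max 1.

    Reveals low-density contralateral links that would otherwise be invisible
    next to the (stronger) ipsilateral ones.  All-zero blocks stay zero.
    """
    vals = m.values.copy()
    n = m.n
    for block in (vals[:, :n], vals[:, n:]):
        mx = block.max(axis=1, keepdims=True)
        np.divide(block, mx, out=block, where=mx > 0)
    return m.copy_with(np.minimum(vals, 1.0), hemisphere_normalized=True)


# ---------------------------------------------------------------------------
# Mirror expansion to a whole-brain graph
# ---------------------------------------------------------------------------

LEFT_PREFIX = "L"
RIGHT_PREFIX = "R"


def node_label(side: str, node_id: int) -> str:
    return f"{side}:{node_id}"


def expand_bilateral(m: BilateralMatrix, keep_self_loops: bool = True) -> nx.DiGraph:
    """Mirror-expand an S x 2N matrix into a 2N-node directed density graph.

    Left-hemisphere sources get their measured rows (ipsi block to left
    targets, contra block to right targets); right-hemisphere rows are the
    mirror image.  Nodes never injected have no out-edges.  Edge attribute
    ``density`` carries the matrix entry; zero entries produce no edge.
    """
    g = nx.DiGraph()
    g.graph["measure"] = m.measure
    for side in (LEFT_PREFIX, RIGHT_PREFIX):
        for nid in m.nodes:
            g.add_node(node_label(side, nid), hemisphere=side, structure_id=nid)
    n = m.n
    for i, src in enumerate(m.source_nodes):
        for j, tgt in enumerate(m.nodes):
            ip, co = m.values[i, j], m.values[i, n + j]
            if src == tgt and not keep_self_loops:
                ip = 0.0
            if ip > 0:
                g.add_edge(node_label("L", src), node_label("L", tgt), density=float(ip))
                g.add_edge(node_label("R", src), node_label("R", tgt), density=float(ip))
            if co > 0:
                g.add_edge(node_label("L", src), node_label("R", tgt), density=float(co))
                g.add_edge(node_label("R", src), node_label("L", tgt), density=float(co))
    return g


def collapse_bilateral(g: nx.DiGraph, m_template: BilateralMatrix) -> BilateralMatrix:
    """Read the left-hemisphere rows of a full graph back into matrix form."""
    n = m_template.n
    vals = np.zeros_like(m_template.values)
    for i, src in enumerate(m_template.source_nodes):
        for j, tgt in enumerate(m_template.nodes):
            e = g.get_edge_data(node_label("L", src), node_label("L", tgt))
            if e:
                vals[i, j] = e["density"]
            e = g.get_edge_data(node_label("L", src), node_label("R", tgt))
            if e:
                vals[i, n + j] = e["density"]
    return m_template.copy_with(vals)


# ---------------------------------------------------------------------------
# Persistence: CSV + JSON sidecar
# ---------------------------------------------------------------------------


def _acronyms(nodes: Sequence[int], tree: Optional[StructureTree]) -> list[str]:
    if tree is None:
        return [str(n) for n in nodes]
    return [tree.get(n).acronym for n in nodes]


def to_frame(m: BilateralMatrix, tree: Optional[StructureTree] = None) -> pd.DataFrame:
    """DataFrame view: ipsi columns labelled ``L:``, contra ``R:``.

    The ``L``/``R`` labels reflect the default all-left injection convention
    under which the ipsilateral block is the left hemisphere.
    """
    acr = _acronyms(m.nodes, tree)
    cols = [f"L:{a}" for a in acr] + [f"R:{a}" for a in acr]
    idx = _acronyms(m.source_nodes, tree)
    return pd.DataFrame(m.values, index=idx, columns=cols)


def save_matrix(
    m: BilateralMatrix, path: str | Path, tree: Optional[StructureTree] = None
) -> None:
    path = Path(path)
    to_frame(m, tree).to_csv(path, float_format="%.12g")
    sidecar = {
        "measure": m.measure,
        "nodes": list(m.nodes),
        "source_nodes": list(m.source_nodes),
        "params": m.params,
    }
    path.with_suffix(path.suffix + ".meta.json").write_text(
        json.dumps(sidecar, indent=1, sort_keys=True) + "\n"
    )


def load_matrix(path: str | Path) -> BilateralMatrix:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".meta.json").read_text())
    df = pd.read_csv(path, index_col=0)
    return BilateralMatrix(
        values=df.to_numpy(dtype=float),
        source_nodes=tuple(sidecar["source_nodes"]),
        nodes=tuple(sidecar["nodes"]),
        measure=sidecar["measure"],
        params=sidecar.get("params", {}),
    )
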