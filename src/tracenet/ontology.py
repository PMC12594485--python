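"""Brain-structure ontology: hierarchy, node lists, and centroid geometry.

The ontology is a rooted tree of brain structures.  Each structure carries a
stereotaxic centroid (micrometers, reference-atlas space) used for distance
computations, and an optional volume used to weight aggregation of raw
structures into network nodes.

A *node list* is an ordered subset of structures chosen to tile the brain
without overlap: no listed structure may be an ancestor of another listed
structure.  The node-list order defines matrix row/column indices everywhere
downstream.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

from .config import MIDLINE_UM, MIRROR_AXIS, logger


class OntologyError(ValueError):
    """Malformed or inconsistent ontology input."""


@dataclass(frozen=True)
class StructureRecord:
    """One brain structure: identity, position in the hierarchy, geometry."""

    structure_id: int
    acronym: str
    name: str
    parent_id: Optional[int]  # None marks the root
    centroid: Optional[tuple[float, float, float]]  # None marks missing
    volume: Optional[float] = None

    def __post_init__(self) -> None:
        if self.centroid is not None:
            if len(self.centroid) != 3 or not all(
                math.isfinite(c) and c >= 0 for c in self.centroid
            ):
                raise OntologyError(
                    f"structure {self.structure_id}: centroid must be three "
                    f"finite non-negative coordinates, got {self.centroid!r}"
                )


class StructureTree:
    """A validated rooted hierarchy of :class:`StructureRecord`."""

    def __init__(self, records: Iterable[StructureRecord]):
        self._records: dict[int, StructureRecord] = {}
        for rec in records:
            if rec.structure_id in self._records:
                raise OntologyError(f"duplicate structure id {rec.structure_id}")
            self._records[rec.structure_id] = rec
        self._by_acronym = {r.acronym: r for r in self._records.values()}
        self._validate()

    def _validate(self) -> None:
        roots = [r for r in self._records.values() if r.parent_id is None]
        if len(roots) != 1:
            raise OntologyError(
                f"tree must have exactly one root, found {len(roots)}"
            )
        self._root = roots[0]
        for rec in self._records.values():
            if rec.parent_id is not None and rec.parent_id not in self._records:
                raise OntologyError(
                    f"structure {rec.structure_id} has unknown parent "
                    f"{rec.parent_id}"
                )
        # Cycle check: walk each parent chain, it must reach the root.
        for rec in self._records.values():
            seen = set()
            cur: Optional[int] = rec.structure_id
            while cur is not None:
                if cur in seen:
                    cycle = " -> ".join(str(s) for s in sorted(seen))
                    raise OntologyError(f"cyclic parent chain involving {cycle}")
                seen.add(cur)
                cur = self._records[cur].parent_id

    # -- lookup ----------------------------------------------------------

    def __len__(self) -> int:
        return len(self._records)

    def __contains__(self, structure_id: int) -> bool:
        return structure_id in self._records

    def __iter__(self) -> Iterator[StructureRecord]:
        return iter(self._records.values())

    @property
    def root(self) -> StructureRecord:
        return self._root

    def get(self, structure_id: int) -> StructureRecord:
        try:
            return self._records[structure_id]
        except KeyError:
            raise KeyError(f"unknown structure id {structure_id}") from None

    def resolve(self, key: int | str) -> StructureRecord:
        """Look a structure up by id or by acronym."""
        if isinstance(key, str) and key in self._by_acronym:
            return self._by_acronym[key]
        return self.get(int(key))

    def ancestors(self, structure_id: int, include_self: bool = True) -> list[int]:
        """Ancestor path from the structure (optionally inclusive) to the root."""
        rec = self.get(structure_id)
        path = [rec.structure_id] if include_self else []
        cur = rec.parent_id
        while cur is not None:
            path.append(cur)
            cur = self._records[cur].parent_id
        return path

    def is_ancestor(self, candidate: int, of: int) -> bool:
        """True if ``candidate`` is a strict ancestor of ``of``."""
        return candidate in self.ancestors(of, include_self=False)

    def ancestor_at_depth(self, structure_id: int, depth: int) -> int:
        """The ancestor sitting ``depth`` levels below the root (0 = root)."""
        path = self.ancestors(structure_id)  # leaf .. root
        path.reverse()  # root .. leaf
        return path[min(depth, len(path) - 1)]


@dataclass(frozen=True)
class NodeList:
    """Ordered sequence of structure ids defining matrix axes."""

    node_ids: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(set(self.node_ids)) != len(self.node_ids):
            raise OntologyError("node list contains duplicate ids")

    def __len__(self) -> int:
        return len(self.node_ids)

    def __iter__(self) -> Iterator[int]:
        return iter(self.node_ids)

    def __contains__(self, node_id: int) -> bool:
        return node_id in self._index

    @property
    def _index(self) -> dict[int, int]:
        # cached lazily on the instance despite frozen dataclass
        idx = self.__dict__.get("_index_cache")
        if idx is None:
            idx = {n: i for i, n in enumerate(self.node_ids)}
            object.__setattr__(self, "_index_cache", idx)
        return idx

    def index(self, node_id: int) -> int:
        try:
            return self._index[node_id]
        except KeyError:
            raise KeyError(f"structure {node_id} is not in the node list") from None


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_ROOT_MARKERS = (None, "", "null", "None", -1, "-1")


def _coerce_parent(value: object) -> Optional[int]:
    if value in _ROOT_MARKERS:
        return None
    return int(value)  # type: ignore[arg-type]


def _coerce_centroid(x: object, y: object, z: object) -> Optional[tuple[float, float, float]]:
    vals = (x, y, z)
    if any(v in (None, "") for v in vals):
        return None
    triple = tuple(float(v) for v in vals)  # type: ignore[arg-type]
    if any(math.isnan(v) for v in triple):
        return None
    return triple  # type: ignore[return-value]


def _record_from_mapping(row: dict) -> StructureRecord:
    try:
        sid = int(row["id"])
    except (KeyError, TypeError, ValueError) as exc:
        raise OntologyError(f"ontology row missing a valid 'id': {row!r}") from exc
    vol = row.get("volume")
    return StructureRecord(
        structure_id=sid,
        acronym=str(row.get("acronym", str(sid))),
        name=str(row.get("name", "")),
        parent_id=_coerce_parent(row.get("parent_id")),
        centroid=_coerce_centroid(row.get("x"), row.get("y"), row.get("z")),
        volume=None if vol in (None, "") else float(vol),
    )


def load_ontology(path: str | Path) -> StructureTree:
    """Load a structure hierarchy from a JSON array or a CSV file.

    Both dialects use the column names
    ``id, acronym, name, parent_id, x, y, z, volume``; an empty/null
    ``parent_id`` marks the root, and missing coordinates yield a record with
    an explicit missing-centroid marker (``centroid is None``).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".csv":
        with open(path, newline="") as fh:
            rows = list(csv.DictReader(fh))
    else:
        try:
            rows = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise OntologyError(f"cannot parse ontology file {path}: {exc}") from exc
        if not isinstance(rows, list):
            raise OntologyError(f"ontology JSON must be an array, got {type(rows)}")
    return StructureTree(_record_from_mapping(row) for row in rows)


def save_ontology(tree: StructureTree, path: str | Path) -> None:
    """Write a tree back to the JSON dialect accepted by :func:`load_ontology`."""
    rows = []
    for rec in tree:
        x, y, z = rec.centroid if rec.centroid is not None else (None, None, None)
        rows.append(
            {
                "id": rec.structure_id,
                "acronym": rec.acronym,
                "name": rec.name,
                "parent_id": rec.parent_id,
                "x": x,
                "y": y,
                "z": z,
                "volume": rec.volume,
            }
        )
    Path(path).write_text(json.dumps(rows, indent=1, sort_keys=True) + "\n")


def load_nodelist(path: str | Path, tree: StructureTree) -> NodeList:
    """Read a node list: one structure id or acronym per line."""
    ids = []
    for line in Path(path).read_text().splitlines():
        token = line.strip()
        if not token or token.startswith("#"):
            continue
        ids.append(tree.resolve(token).structure_id)
    return NodeList(tuple(ids))


def save_nodelist(nodes: NodeList, path: str | Path) -> None:
    Path(path).write_text("\n".join(str(n) for n in nodes) + "\n")


# ---------------------------------------------------------------------------
# Node-list semantics
# ---------------------------------------------------------------------------


def validate_nodelist(nodes: NodeList, tree: StructureTree) -> list[str]:
    """Check the non-overlap contract; return a list of violation messages.

    An empty report means no listed node is an ancestor of another listed
    node, which guarantees that :func:`nearest_node_ancestor` has at most one
    candidate for any structure.
    """
    violations: list[str] = []
    listed = set()
    for nid in nodes:
        if nid not in tree:
            raise KeyError(f"node list references unknown structure {nid}")
        listed.add(nid)
    for nid in nodes:
        for anc in tree.ancestors(nid, include_self=False):
            if anc in listed:
                violations.append(
                    f"node {nid} overlaps listed ancestor {anc}"
                )
    return violations


def nearest_node_ancestor(
    structure_id: int, nodes: NodeList, tree: StructureTree
) -> Optional[int]:
    """Map an arbitrary structure to its node-list node, or None.

    Climbs the ancestor path starting at the structure itself and returns the
    first member of the node list encountered.  Under the non-overlap
    invariant this member is unique.
    """
    for anc in tree.ancestors(structure_id, include_self=True):
        if anc in nodes:
            return anc
    return None


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------


class MissingCentroidError(ValueError):
    """A distance was requested for a structure without a centroid."""


def mirror_centroid(
    centroid: Sequence[float],
    midline: float = MIDLINE_UM,
    axis: int = MIRROR_AXIS,
) -> tuple[float, float, float]:
    """Reflect a centroid across the mediolateral midline plane."""
    out = list(centroid)
    out[axis] = 2.0 * midline - out[axis]
    return tuple(out)  # type: ignore[return-value]


def centroid_distance(
    node_a: int,
    node_b: int,
    same_hemisphere: bool,
    tree: StructureTree,
    midline: float = MIDLINE_UM,
    axis: int = MIRROR_AXIS,
) -> float:
    """Euclidean distance in micrometers between two structure centroids.

    For cross-hemisphere pairs the second centroid is mirrored across the
    midline plane before measuring, so a structure's distance to its own
    contralateral homolog is twice its distance from the midline.
    """
    ca = tree.get(node_a).centroid
    cb = tree.get(node_b).centroid
    for nid, c in ((node_a, ca), (node_b, cb)):
        if c is None:
            raise MissingCentroidError(f"structure {nid} has no centroid")
    if not same_hemisphere:
        cb = mirror_centroid(cb, midline=midline, axis=axis)
    return math.dist(ca, cb)
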