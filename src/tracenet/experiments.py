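"""Tracer-experiment records: parsing, QC, normalization, filtering.

Each anterograde-tracer experiment quantifies, per brain structure and per
hemisphere, four projection measures (density, intensity, energy, volume)
segmented from fluorescence imaging.  This module turns raw JSON records into
normalized adjacency-row candidates:

1. *Hemisphere assignment* — the injection hemisphere must win all three
   criteria: (a) more structures flagged ``is_injection``, (b) a larger total
   projection-density sum, and (c) possession of the single highest-density
   structure.  Experiments failing any criterion (or tying) are rejected.
2. *Injection identification* — ipsilateral entries are aggregated onto the
   node list; the node with maximal aggregated density is the injection site
   (ties broken by node-list order).
3. *Normalization* — every measure is divided by its value at the injection
   site, pinning the injection site to 1.0 and (after clipping) confining all
   values to [0, 1].
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Optional, Sequence

import numpy as np

from .config import CONTRA, HEMISPHERES, IPSI, LEFT, MEASURES, OTSU_BINS, RIGHT, logger
from .ontology import NodeList, StructureTree, nearest_node_ancestor


class ParseError(ValueError):
    """Raw experiment JSON is structurally unusable."""


class ExperimentRejected(Exception):
    """An experiment failed a QC rule; ``reasons`` lists the failing codes."""

    def __init__(self, experiment_id, reasons: Sequence[str]):
        self.experiment_id = experiment_id
        self.reasons = list(reasons)
        super().__init__(f"experiment {experiment_id} rejected: {', '.join(self.reasons)}")


@dataclass(frozen=True)
class ProjectionEntry:
    """Per-structure, per-hemisphere segmentation readout."""

    structure_id: int
    hemisphere: str  # "left" | "right"
    is_injection: bool
    density: float
    intensity: float
    energy: float
    volume: float

    def measure(self, name: str) -> float:
        return getattr(self, name)


@dataclass
class ExperimentRecord:
    experiment_id: int
    entries: list[ProjectionEntry]
    metadata: dict = field(default_factory=dict)


@dataclass
class NormalizedExperiment:
    """One adjacency-row candidate.

    ``values[measure][(node_id, "ipsi"|"contra")]`` holds the normalized
    measure; a measure whose injection-site value was zero maps to ``None``
    (unavailable).  Absent keys mean zero signal.
    """

    experiment_id: int
    injection_node: int
    injection_side: str
    values: dict[str, Optional[dict[tuple[int, str], float]]]
    metadata: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

_HEMI_CODES = {1: LEFT, 2: RIGHT, "left": LEFT, "right": RIGHT, "L": LEFT, "R": RIGHT}

_MEASURE_KEYS = {
    "density": "projection_density",
    "intensity": "projection_intensity",
    "energy": "projection_energy",
    "volume": "projection_volume",
}

_META_KEYS = ("sex", "strain", "transgenic_line", "injection_volume")


def parse_experiment(raw: dict) -> ExperimentRecord:
    """Parse one raw JSON experiment record.

    Expects a top-level ``id`` plus a ``structure_unionizes`` list whose items
    carry ``structure_id``, ``hemisphere_id`` (1=left, 2=right), an
    ``is_injection`` flag and the four ``projection_*`` measures.  Missing
    optional measures default to 0 with a logged note.
    """
    if "id" not in raw:
        raise ParseError("experiment record has no 'id'")
    entries = []
    defaulted = 0
    for item in raw.get("structure_unionizes", []):
        if "hemisphere_id" not in item and "hemisphere" not in item:
            raise ParseError(
                f"experiment {raw['id']}: entry missing hemisphere label: {item!r}"
            )
        hemi_raw = item.get("hemisphere_id", item.get("hemisphere"))
        try:
            hemi = _HEMI_CODES[hemi_raw]
        except KeyError:
            raise ParseError(
                f"experiment {raw['id']}: unknown hemisphere {hemi_raw!r}"
            ) from None
        vals = {}
        for name, key in _MEASURE_KEYS.items():
            if key in item:
                vals[name] = float(item[key])
            else:
                vals[name] = 0.0
                defaulted += 1
        if any(v < 0 for v in vals.values()):
            raise ParseError(
                f"experiment {raw['id']}: negative projection measure in {item!r}"
            )
        entries.append(
            ProjectionEntry(
                structure_id=int(item["structure_id"]),
                hemisphere=hemi,
                is_injection=bool(item.get("is_injection", False)),
                **vals,
            )
        )
    if defaulted:
        logger.warning(
            "experiment %s: %d missing measures defaulted to 0", raw["id"], defaulted
        )
    metadata = {k: raw[k] for k in _META_KEYS if k in raw}
    return ExperimentRecord(experiment_id=int(raw["id"]), entries=entries, metadata=metadata)


def serialize_experiment(rec: ExperimentRecord) -> dict:
    """Inverse of :func:`parse_experiment` (left hemisphere code 1, right 2)."""
    codes = {LEFT: 1, RIGHT: 2}
    return {
        "id": rec.experiment_id,
        **{k: rec.metadata[k] for k in _META_KEYS if k in rec.metadata},
        "structure_unionizes": [
            {
                "structure_id": e.structure_id,
                "hemisphere_id": codes[e.hemisphere],
                "is_injection": e.is_injection,
                "projection_density": e.density,
                "projection_intensity": e.intensity,
                "projection_energy": e.energy,
                "projection_volume": e.volume,
            }
            for e in rec.entries
        ],
    }


# ---------------------------------------------------------------------------
# Hemisphere assignment (QC criteria a-c)
# ---------------------------------------------------------------------------


def assign_hemispheres(rec: ExperimentRecord) -> tuple[str, str]:
    """Determine (ipsi, contra) hemispheres, or reject the experiment.

    The ipsilateral (injection) hemisphere must strictly win all three
    criteria: (a) count of ``is_injection`` structures, (b) total projection
    density summed over all entries, and (c) location of the single
    highest-density structure.  Any criterion that ties or points the other
    way adds a reason code to the rejection.
    """
    inj_counts = {h: 0 for h in HEMISPHERES}
    dens_sums = {h: 0.0 for h in HEMISPHERES}
    for e in rec.entries:
        if e.is_injection:
            inj_counts[e.hemisphere] += 1
        dens_sums[e.hemisphere] += e.density
    if sum(inj_counts.values()) == 0:
        raise ExperimentRejected(rec.experiment_id, ["no-injection"])

    def winner(scores: dict[str, float]) -> Optional[str]:
        if scores[LEFT] > scores[RIGHT]:
            return LEFT
        if scores[RIGHT] > scores[LEFT]:
            return RIGHT
        return None  # tie

    win_a = winner(inj_counts)
    win_b = winner(dens_sums)
    max_d = max(e.density for e in rec.entries)
    sides_with_max = {e.hemisphere for e in rec.entries if e.density == max_d}
    win_c = sides_with_max.pop() if len(sides_with_max) == 1 else None

    votes = {"a": win_a, "b": win_b, "c": win_c}
    decided = {v for v in votes.values() if v is not None}
    if len(decided) == 1 and None not in votes.values():
        ipsi = decided.pop()
        contra = RIGHT if ipsi == LEFT else LEFT
        return ipsi, contra
    # Failing criteria: ties, plus any criterion disagreeing with the rest.
    majority = max(decided, key=lambda s: sum(v == s for v in votes.values())) if decided else None
    failing = [f"criterion-{k}" for k, v in sorted(votes.items()) if v is None or v != majority]
    raise ExperimentRejected(rec.experiment_id, failing or ["criteria-tie"])


# ---------------------------------------------------------------------------
# Aggregation onto the node list
# ---------------------------------------------------------------------------


def _aggregate_side(
    rec: ExperimentRecord,
    side: str,
    nodes: NodeList,
    tree: StructureTree,
    measure: str,
    climb: bool = True,
) -> dict[int, float]:
    """Aggregate one hemisphere's raw entries onto node-list nodes.

    Each raw structure maps to the nearest listed ancestor (or only to itself
    when ``climb`` is False).  Several raw structures landing on one node are
    combined by a volume-weighted mean of their measure values, using the
    ontology structure volumes as weights; if any contributing structure lacks
    a volume the mean falls back to unweighted.
    """
    buckets: dict[int, list[tuple[float, Optional[float]]]] = {}
    for e in rec.entries:
        if e.hemisphere != side or e.structure_id not in tree:
            continue
        if climb:
            node = nearest_node_ancestor(e.structure_id, nodes, tree)
        else:
            node = e.structure_id if e.structure_id in nodes else None
        if node is None:
            continue
        buckets.setdefault(node, []).append(
            (e.measure(measure), tree.get(e.structure_id).volume)
        )
    out = {}
    for node, pairs in buckets.items():
        if len(pairs) == 1:  # exact: avoid weighted-mean rounding on singletons
            out[node] = pairs[0][0]
            continue
        vals = np.array([p[0] for p in pairs])
        if all(p[1] is not None for p in pairs):
            w = np.array([p[1] for p in pairs], dtype=float)
            out[node] = float(np.average(vals, weights=w)) if w.sum() > 0 else float(vals.mean())
        else:
            out[node] = float(vals.mean())
    return out


def identify_injection(
    rec: ExperimentRecord,
    ipsi_side: str,
    nodes: NodeList,
    tree: StructureTree,
    climb: bool = True,
) -> int:
    """The ipsilateral node with maximal aggregated projection density."""
    agg = _aggregate_side(rec, ipsi_side, nodes, tree, "density", climb=climb)
    if not agg:
        raise ExperimentRejected(rec.experiment_id, ["unmappable-injection"])
    best = max(agg.values())
    for nid in nodes:  # deterministic tie-break: node-list order
        if nid in agg and agg[nid] == best:
            return nid
    raise AssertionError("unreachable")


def normalize(
    rec: ExperimentRecord,
    injection_node: int,
    ipsi_side: str,
    nodes: NodeList,
    tree: StructureTree,
    climb: bool = True,
) -> NormalizedExperiment:
    """Divide each measure by its injection-site value; clip overshoot to 1.

    A zero injection-site *density* rejects the experiment; a zero
    injection-site value for any other measure marks just that measure's
    mapping unavailable.
    """
    contra_side = RIGHT if ipsi_side == LEFT else LEFT
    values: dict[str, Optional[dict[tuple[int, str], float]]] = {}
    clipped = 0
    for measure in MEASURES:
        ipsi_agg = _aggregate_side(rec, ipsi_side, nodes, tree, measure, climb=climb)
        contra_agg = _aggregate_side(rec, contra_side, nodes, tree, measure, climb=climb)
        ref = ipsi_agg.get(injection_node, 0.0)
        if ref <= 0:
            if measure == "density":
                raise ExperimentRejected(rec.experiment_id, ["zero-injection-density"])
            values[measure] = None
            continue
        vmap: dict[tuple[int, str], float] = {}
        for srel, agg in ((IPSI, ipsi_agg), (CONTRA, contra_agg)):
            for node, v in agg.items():
                x = v / ref
                if x > 1.0:
                    x = 1.0
                    clipped += 1
                if x > 0.0:
                    vmap[(node, srel)] = x
        vmap[(injection_node, IPSI)] = 1.0
        values[measure] = vmap
    if clipped:
        logger.info("experiment %s: clipped %d values > 1", rec.experiment_id, clipped)
    return NormalizedExperiment(
        experiment_id=rec.experiment_id,
        injection_node=injection_node,
        injection_side=ipsi_side,
        values=values,
        metadata=dict(rec.metadata),
    )


def process_experiment(
    rec: ExperimentRecord, nodes: NodeList, tree: StructureTree, climb: bool = True
) -> NormalizedExperiment:
    """Full QC + normalization pipeline for one parsed record."""
    ipsi, _ = assign_hemispheres(rec)
    inj = identify_injection(rec, ipsi, nodes, tree, climb=climb)
    return normalize(rec, inj, ipsi, nodes, tree, climb=climb)


# ---------------------------------------------------------------------------
# Database: a processed collection with QC report
# ---------------------------------------------------------------------------

SCHEMA_VERSION = 1


@dataclass
class Database:
    """Accepted normalized experiments plus the rejection report."""

    experiments: list[NormalizedExperiment] = field(default_factory=list)
    rejections: dict[int, list[str]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.experiments)


def build_database(
    raw_records: Iterable[dict],
    nodes: NodeList,
    tree: StructureTree,
    climb: bool = True,
) -> Database:
    db = Database()
    for raw in raw_records:
        rec = parse_experiment(raw)
        try:
            db.experiments.append(process_experiment(rec, nodes, tree, climb=climb))
        except ExperimentRejected as rej:
            db.rejections[rec.experiment_id] = rej.reasons
    return db


def _ne_to_json(ne: NormalizedExperiment) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "experiment_id": ne.experiment_id,
        "injection_node": ne.injection_node,
        "injection_side": ne.injection_side,
        "metadata": ne.metadata,
        "values": {
            m: None
            if vmap is None
            else {f"{node}:{srel}": v for (node, srel), v in sorted(vmap.items())}
            for m, vmap in ne.values.items()
        },
    }


def _ne_from_json(obj: dict) -> NormalizedExperiment:
    values = {}
    for m, vmap in obj["values"].items():
        if vmap is None:
            values[m] = None
        else:
            out = {}
            for key, v in vmap.items():
                node, srel = key.rsplit(":", 1)
                out[(int(node), srel)] = v
            values[m] = out
    return NormalizedExperiment(
        experiment_id=obj["experiment_id"],
        injection_node=obj["injection_node"],
        injection_side=obj["injection_side"],
        values=values,
        metadata=obj.get("metadata", {}),
    )


def save_database(db: Database, directory: str | Path) -> None:
    """One JSON store per experiment plus an index file."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for ne in db.experiments:
        path = directory / f"experiment_{ne.experiment_id}.json"
        path.write_text(json.dumps(_ne_to_json(ne), indent=1, sort_keys=True) + "\n")
    index = {
        "schema_version": SCHEMA_VERSION,
        "experiment_ids": sorted(ne.experiment_id for ne in db.experiments),
        "rejections": {str(k): v for k, v in sorted(db.rejections.items())},
    }
    (directory / "index.json").write_text(json.dumps(index, indent=1, sort_keys=True) + "\n")


def load_database(directory: str | Path) -> Database:
    directory = Path(directory)
    index = json.loads((directory / "index.json").read_text())
    exps = []
    for eid in index["experiment_ids"]:
        obj = json.loads((directory / f"experiment_{eid}.json").read_text())
        exps.append(_ne_from_json(obj))
    return Database(
        experiments=exps,
        rejections={int(k): v for k, v in index.get("rejections", {}).items()},
    )


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

_FILTER_KEYS = {"sex", "strain", "transgenic_line", "injection_node", "injection_volume_range"}


def filter_experiments(
    experiments: Iterable[NormalizedExperiment], **criteria
) -> list[NormalizedExperiment]:
    """Select experiments satisfying the conjunction of metadata criteria.

    Supported keys: ``sex``, ``strain``, ``transgenic_line``,
    ``injection_node`` and ``injection_volume_range`` (an inclusive
    ``(lo, hi)`` pair in microliters).
    """
    unknown = set(criteria) - _FILTER_KEYS
    if unknown:
        raise ValueError(f"unknown filter criteria: {sorted(unknown)}")

    def keep(ne: NormalizedExperiment) -> bool:
        for key, want in criteria.items():
            if key == "injection_node":
                if ne.injection_node != want:
                    return False
            elif key == "injection_volume_range":
                lo, hi = want
                vol = ne.metadata.get("injection_volume")
                if vol is None or not (lo <= vol <= hi):
                    return False
            else:
                if ne.metadata.get(key) != want:
                    return False
        return True

    return [ne for ne in experiments if keep(ne)]


# ---------------------------------------------------------------------------
# Per-experiment map utilities
# ---------------------------------------------------------------------------


def auto_threshold(ne: NormalizedExperiment, measure: str = "density") -> float:
    """Otsu threshold over the nonzero values of one experiment's map.

    The two-class between-variance-maximizing threshold is computed on a
    256-bin histogram of the nonzero values (zeros carry no signal and are
    excluded by contract).  A constant nonzero map returns that constant.
    """
    vmap = ne.values.get(measure)
    if not vmap:
        raise ValueError("empty-map")
    vals = np.array([v for v in vmap.values() if v > 0], dtype=float)
    if vals.size == 0:
        raise ValueError("empty-map")
    if np.all(vals == vals[0]):
        return float(vals[0])
    from skimage.filters import threshold_otsu

    return float(threshold_otsu(vals, nbins=OTSU_BINS))


def filtermap(ne: NormalizedExperiment, threshold: float, measure: str = "density") -> NormalizedExperiment:
    """Zero out map values below ``threshold`` (values >= threshold kept)."""
    vmap = ne.values.get(measure) or {}
    kept = {k: v for k, v in vmap.items() if v >= threshold}
    values = dict(ne.values)
    values[measure] = kept
    return NormalizedExperiment(
        experiment_id=ne.experiment_id,
        injection_node=ne.injection_node,
        injection_side=ne.injection_side,
        values=values,
        metadata=dict(ne.metadata),
    )


def cross_correlate(
    a: NormalizedExperiment, b: NormalizedExperiment, measure: str = "density"
) -> float:
    """Pearson correlation of two maps over the union of their keys.

    Keys present in only one map contribute 0 for the other.  Returns NaN
    (an undefined marker) when fewer than two keys exist or either map has
    zero variance.
    """
    amap = a.values.get(measure) or {}
    bmap = b.values.get(measure) or {}
    keys = sorted(set(amap) | set(bmap))
    if len(keys) < 2:
        return float("nan")
    x = np.array([amap.get(k, 0.0) for k in keys])
    y = np.array([bmap.get(k, 0.0) for k in keys])
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])
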