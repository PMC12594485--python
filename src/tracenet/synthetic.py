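"""Synthetic ontologies, ground-truth connectomes, and tracer experiments.

The generator emulates the record shape produced by segmenting anterograde
viral-tracer imaging: per-structure, per-hemisphere unionize entries carrying
four projection measures and an ``is_injection`` flag, wrapped in JSON with
animal metadata.  Ground-truth connectivity is drawn with a Bernoulli edge
support biased toward the ipsilateral hemisphere, and nonzero strengths from
a lognormal distribution truncated to [0, 1] — the distribution family that
mesoscale cortico-cortical projection strengths are known to follow.

Default generator settings mirror a densely connected, ipsilaterally
dominated brain: edge density 0.9 and ipsilateral bias 0.85.  Noise is
additive Gaussian on densities, truncated to [0, 1] — the simplest model
that exercises replicate averaging; intensity, energy and volume are
deterministic scaled copies of density, since density drives all default
analyses.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .build import BilateralMatrix
from .config import LEFT, RIGHT
from .ontology import (
    NodeList,
    StructureRecord,
    StructureTree,
    save_nodelist,
    save_ontology,
)

#: Deterministic multipliers turning a density into the other three measures.
MEASURE_SCALES = {"intensity": 50.0, "energy": 20.0, "volume": 0.1}

#: Default coordinate box (micrometers): AP x DV x ML extents of a mouse brain.
DEFAULT_BOX = (13200.0, 8000.0, 11400.0)


# ---------------------------------------------------------------------------
# Ontology fixtures
# ---------------------------------------------------------------------------


def make_tree(
    n_nodes: int,
    depth: int = 3,
    seed: int = 0,
    box: tuple[float, float, float] = DEFAULT_BOX,
) -> tuple[StructureTree, NodeList, dict[int, str]]:
    """Random structure hierarchy whose leaves form the node list.

    Builds ``depth`` internal levels below the root, then hangs ``n_nodes``
    leaves off the deepest level.  Leaves are pairwise non-overlapping by
    construction; the macro grouping maps each leaf to its depth-1 ancestor.
    Centroids are uniform in ``box``; identical seeds give identical trees.
    """
    if n_nodes < 1:
        raise ValueError("n_nodes must be >= 1")
    rng = np.random.default_rng(seed)
    records = []
    next_id = 1

    def add(acronym: str, parent: Optional[int]) -> int:
        nonlocal next_id
        sid = next_id
        next_id += 1
        centroid = tuple(float(rng.uniform(0, b)) for b in box)
        records.append(
            StructureRecord(
                structure_id=sid,
                acronym=acronym,
                name=f"structure {acronym}",
                parent_id=parent,
                centroid=centroid,
                volume=float(rng.uniform(0.5, 5.0) * 1e8),
            )
        )
        return sid

    root = add("ROOT", None)
    if n_nodes == 1 and depth <= 1:
        nodelist = NodeList((add("N001", root),))
        tree = StructureTree(records)
        return tree, nodelist, {nodelist.node_ids[0]: "ROOT"}

    levels: list[list[int]] = [[root]]
    for lvl in range(1, max(depth, 2)):
        width = min(max(2, n_nodes // 4), 6) if lvl == 1 else max(2, len(levels[-1]))
        ids = [
            add(f"D{lvl}_{i:02d}", int(rng.choice(levels[-1])))
            for i in range(width)
        ]
        levels.append(ids)
    leaf_parents = levels[-1]
    leaves = [
        add(f"N{i:03d}", int(rng.choice(leaf_parents))) for i in range(n_nodes)
    ]
    tree = StructureTree(records)
    nodelist = NodeList(tuple(leaves))
    grouping = {
        leaf: tree.get(tree.ancestor_at_depth(leaf, 1)).acronym for leaf in leaves
    }
    return tree, nodelist, grouping


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------


@dataclass
class GroundTruth:
    """Planted bilateral connectome with everything needed to test recovery."""

    nodes: NodeList
    matrix: BilateralMatrix  # N x 2N, ipsi self-entries = 1
    tree: StructureTree
    grouping: dict[int, str]


def make_ground_truth(
    nodes: NodeList,
    tree: StructureTree,
    grouping: Optional[dict[int, str]] = None,
    edge_density: float = 0.9,
    ipsi_bias: float = 0.85,
    lognormal_mu: float = -2.0,
    lognormal_sigma: float = 1.0,
    contra_strength: float = 0.5,
    seed: int = 0,
) -> GroundTruth:
    """Draw a random bilateral connectome.

    Edge support is Bernoulli with per-hemisphere probabilities
    ``p_ipsi = min(1, 2 * edge_density * ipsi_bias)`` and
    ``p_contra = min(1, 2 * edge_density * (1 - ipsi_bias))``, so the
    expected overall density is ``edge_density`` and the expected fraction of
    ipsilateral edges equals ``ipsi_bias`` whenever neither probability
    saturates.  Nonzero strengths are lognormal(mu, sigma) truncated to
    [0, 1]; the ipsilateral self-entry (injection-site density) is 1.

    Cross-hemisphere projections are systematically weaker than same-side
    ones, so contralateral strengths are scaled by ``contra_strength``; in
    addition every row's contralateral mass is forced strictly below its
    ipsilateral mass (rescaled on the rare draws that violate it), which
    guarantees simulated experiments satisfy the hemisphere QC criteria.
    """
    if not (0 <= edge_density <= 1 and 0 <= ipsi_bias <= 1):
        raise ValueError("edge_density and ipsi_bias must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n = len(nodes)
    p_ipsi = min(1.0, 2.0 * edge_density * ipsi_bias)
    p_contra = min(1.0, 2.0 * edge_density * (1.0 - ipsi_bias))
    support = np.hstack(
        [
            rng.random((n, n)) < p_ipsi,
            rng.random((n, n)) < p_contra,
        ]
    )
    # Truncation by resampling keeps strengths strictly below 1, so the
    # injection self-entry (exactly 1) is always the unique hemisphere-wide
    # density maximum and uncorrupted records pass QC criterion (c).
    weights = rng.lognormal(mean=lognormal_mu, sigma=lognormal_sigma, size=(n, 2 * n))
    for _ in range(100):
        over = weights >= 1.0
        if not over.any():
            break
        weights[over] = rng.lognormal(lognormal_mu, lognormal_sigma, size=int(over.sum()))
    weights = np.minimum(weights, 0.999999)
    weights[:, n:] *= contra_strength
    values = np.where(support, weights, 0.0)
    np.fill_diagonal(values[:, :n], 1.0)
    ipsi_mass = values[:, :n].sum(axis=1)
    contra_mass = values[:, n:].sum(axis=1)
    bad = contra_mass >= ipsi_mass
    if bad.any():
        scale = 0.9 * ipsi_mass[bad] / contra_mass[bad]
        values[bad, n:] *= scale[:, None]
    matrix = BilateralMatrix(
        values=values,
        source_nodes=tuple(nodes),
        nodes=tuple(nodes),
        measure="density",
        params={"edge_density": edge_density, "ipsi_bias": ipsi_bias, "seed": seed},
    )
    return GroundTruth(nodes=nodes, matrix=matrix, tree=tree, grouping=grouping or {})


# ---------------------------------------------------------------------------
# Experiment simulation
# ---------------------------------------------------------------------------


def simulate_experiments(
    gt: GroundTruth,
    replicates_per_site: int = 1,
    noise_sd: float = 0.0,
    injection_side_policy: str = "all-left",
    metadata_policy: Optional[dict] = None,
    seed: int = 0,
    corruption: Optional[str] = None,
) -> list[dict]:
    """Emit raw JSON experiment records sampled around the ground truth.

    One record per (source node, replicate): densities are the true row plus
    additive Gaussian noise clipped to [0, 1]; intensity/energy/volume are
    scaled copies of density.  The injection structure gets ``is_injection``
    and, being the self-entry, carries the maximal density, so uncorrupted
    records pass the hemisphere QC criteria by construction.

    ``injection_side_policy`` is ``"all-left"`` (default) or ``"random"``.
    ``metadata_policy`` may fix metadata values (``{"sex": "M", ...}``) or
    request random sexes (``{"sex_proportions": {"M": 0.6, "F": 0.4}}``).
    ``corruption="split-injection"`` plants a second injection flag on the
    opposite hemisphere so QC must reject the record.
    """
    if replicates_per_site < 1:
        raise ValueError("replicates_per_site must be >= 1")
    rng = np.random.default_rng(seed)
    metadata_policy = metadata_policy or {}
    records = []
    n = len(gt.nodes)
    node_ids = list(gt.nodes)
    for i, src in enumerate(node_ids):
        for rep in range(replicates_per_site):
            if injection_side_policy == "all-left":
                ipsi = LEFT
            elif injection_side_policy == "random":
                ipsi = LEFT if rng.random() < 0.5 else RIGHT
            else:
                raise ValueError(f"unknown injection side policy {injection_side_policy!r}")
            contra = RIGHT if ipsi == LEFT else LEFT
            side_code = {LEFT: 1, RIGHT: 2}
            row = gt.matrix.values[i].copy()
            if noise_sd > 0:
                row = np.clip(row + rng.normal(0.0, noise_sd, size=row.shape), 0.0, 1.0)
            entries = []
            for j, tgt in enumerate(node_ids):
                for offset, side in ((0, ipsi), (n, contra)):
                    d = row[j + offset]
                    if d <= 0 and not (tgt == src and offset == 0):
                        continue
                    entries.append(
                        {
                            "structure_id": tgt,
                            "hemisphere_id": side_code[side],
                            "is_injection": bool(tgt == src and offset == 0),
                            "projection_density": float(d),
                            "projection_intensity": float(d * MEASURE_SCALES["intensity"]),
                            "projection_energy": float(d * MEASURE_SCALES["energy"]),
                            "projection_volume": float(d * MEASURE_SCALES["volume"]),
                        }
                    )
            if corruption == "split-injection":
                entries.append(
                    {
                        "structure_id": src,
                        "hemisphere_id": side_code[contra],
                        "is_injection": True,
                        "projection_density": 0.5,
                        "projection_intensity": 0.5 * MEASURE_SCALES["intensity"],
                        "projection_energy": 0.5 * MEASURE_SCALES["energy"],
                        "projection_volume": 0.5 * MEASURE_SCALES["volume"],
                    }
                )
            elif corruption is not None:
                raise ValueError(f"unknown corruption {corruption!r}")
            sex = metadata_policy.get("sex", "M")
            props = metadata_policy.get("sex_proportions")
            if props:
                labels = sorted(props)
                p = np.array([props[k] for k in labels], dtype=float)
                sex = str(rng.choice(labels, p=p / p.sum()))
            records.append(
                {
                    "id": 1000 * (i + 1) + rep,
                    "sex": sex,
                    "strain": metadata_policy.get("strain", "C57BL/6J"),
                    "transgenic_line": metadata_policy.get("transgenic_line", ""),
                    "injection_volume": metadata_policy.get("injection_volume", 0.1),
                    "structure_unionizes": entries,
                }
            )
    return records


def write_fixture_dir(
    gt: GroundTruth,
    records: list[dict],
    directory: str | Path,
) -> None:
    """Materialize a fixture study: ontology, node list, truth matrix, records."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    save_ontology(gt.tree, directory / "ontology.json")
    save_nodelist(gt.nodes, directory / "nodelist.txt")
    from .build import save_matrix

    save_matrix(gt.matrix, directory / "truth.csv", gt.tree)
    for rec in records:
        (directory / f"raw_{rec['id']}.json").write_text(
            json.dumps(rec, indent=1, sort_keys=True) + "\n"
        )


# ---------------------------------------------------------------------------
# The fixed worked example
# ---------------------------------------------------------------------------


def worked_example_graph() -> pd.DataFrame:
    """The fixed 4-node density network used throughout the documentation.

    Densities: A->B 0.5, B->C 0.5, A->C 0.2, C->D 1.0.  With synapse factor
    0 the traversal weights are 2, 2, 5 and 1, giving the hand-checkable
    table: weighted distance A->D = 5 via A-B-C-D; shortest A->C runs through
    B (length 4, two hops) while the direct edge costs 5; betweenness of B
    and C is 1/3 each under ordered-pair normalization.
    """
    labels = ["A", "B", "C", "D"]
    m = pd.DataFrame(0.0, index=labels, columns=labels)
    m.loc["A", "B"] = 0.5
    m.loc["B", "C"] = 0.5
    m.loc["A", "C"] = 0.2
    m.loc["C", "D"] = 1.0
    return m
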