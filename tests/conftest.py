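import pytest

import tracenet as tn


@pytest.fixture
def small_tree():
    """Root with two macro areas, each holding leaf structures.

    Layout (ids):
        1 ROOT
          2 CTX   -> leaves 4, 5
          3 TH    -> leaf 6; 6 has child 7 (a sub-structure below the node level)
    """
    recs = [
        tn.StructureRecord(1, "ROOT", "root", None, (100.0, 100.0, 100.0), 10.0),
        tn.StructureRecord(2, "CTX", "cortex", 1, (200.0, 100.0, 100.0), 5.0),
        tn.StructureRecord(3, "TH", "thalamus", 1, (300.0, 100.0, 100.0), 5.0),
        tn.StructureRecord(4, "CTX-a", "cortex a", 2, (0.0, 0.0, 0.0), 2.0),
        tn.StructureRecord(5, "CTX-b", "cortex b", 2, (3000.0, 4000.0, 0.0), 2.0),
        tn.StructureRecord(6, "TH-a", "thalamus a", 3, (500.0, 500.0, 6700.0), 2.0),
        tn.StructureRecord(7, "TH-a1", "thalamus a sub", 6, (500.0, 500.0, 6600.0), 1.0),
    ]
    return tn.StructureTree(recs)


@pytest.fixture
def small_nodes():
    return tn.NodeList((4, 5, 6))


@pytest.fixture
def g1_densities():
    """The fixed 4-node worked-example density matrix."""
    return tn.worked_example_graph()


@pytest.fixture
def g1_graph(g1_densities):
    """Worked example as a traversal-weight graph (synapse factor 0)."""
    return tn.edge_weight_graph(g1_densities)


@pytest.fixture
def fixture_study():
    """A small noise-free synthetic study with its ground truth."""
    tree, nodes, grouping = tn.make_tree(8, seed=11)
    gt = tn.make_ground_truth(nodes, tree, grouping, seed=11)
    records = tn.simulate_experiments(gt, replicates_per_site=1, noise_sd=0.0, seed=11)
    return gt, records
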