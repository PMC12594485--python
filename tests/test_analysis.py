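import itertools
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import tracenet as tn
from oracles import (
    oracle_betweenness,
    oracle_dos,
    oracle_k_shortest,
    oracle_shortest,
    oracle_weighted_dos,
    random_density_graph,
)


class TestDegrees:
    def test_unilateral_row_column_sums(self):
        m = pd.DataFrame([[1.0, 0.5], [0.0, 1.0]], index=["a", "b"], columns=["a", "b"])
        deg = tn.degrees(m)
        assert list(deg["out_degree"]) == [1.5, 1.0]
        assert list(deg["in_degree"]) == [1.0, 1.5]

    def test_empty_matrix_all_zero(self):
        m = pd.DataFrame(np.zeros((3, 3)), index=list("abc"), columns=list("abc"))
        deg = tn.degrees(m)
        assert (deg == 0).all().all()

    def test_mass_conservation(self, fixture_study):
        gt, _ = fixture_study
        deg = tn.degrees(gt.matrix)
        total = gt.matrix.values.sum()
        assert deg["in_degree"].sum() == pytest.approx(total)
        assert deg["out_degree"].sum() == pytest.approx(total)

    def test_diagonal_exclusion_flag(self, fixture_study):
        gt, _ = fixture_study
        with_d = tn.degrees(gt.matrix)
        without = tn.degrees(gt.matrix, include_diagonal=False)
        n_sources = len(gt.matrix.source_nodes)
        # every ipsi self-entry is 1.0 in the ground truth
        assert with_d["out_degree"].sum() - without["out_degree"].sum() == pytest.approx(n_sources)


class TestNodeRatios:
    def test_balanced_node_ratio_one(self):
        m = tn.BilateralMatrix(
            values=np.array([[0.0, 0.5, 0.0, 0.0], [0.5, 0.0, 0.0, 0.0]]),
            source_nodes=(4, 5), nodes=(4, 5),
        )
        ratios = tn.node_ratios(m)
        assert ratios.loc[4, "convergence_ratio"] == pytest.approx(1.0)

    def test_zero_contra_block(self):
        m = tn.BilateralMatrix(values=np.array([[1.0, 0.5, 0.0, 0.0]]),
                               source_nodes=(4,), nodes=(4, 5))
        assert tn.node_ratios(m).loc[4, "hemisphere_ratio"] == 0.0

    def test_half_contralateral_output(self):
        m = tn.BilateralMatrix(values=np.array([[0.5, 0.0, 0.0, 0.5]]),
                               source_nodes=(4,), nodes=(4, 5))
        assert tn.node_ratios(m).loc[4, "hemisphere_ratio"] == pytest.approx(0.5)

    def test_zero_out_degree_undefined(self):
        m = tn.BilateralMatrix(values=np.array([[0.0, 0.0, 0.0, 0.0]]),
                               source_nodes=(4,), nodes=(4, 5))
        ratios = tn.node_ratios(m)
        assert math.isnan(ratios.loc[4, "convergence_ratio"])
        assert math.isnan(ratios.loc[4, "hemisphere_ratio"])


class TestEdgeWeightGraph:
    def test_inverse_density_weight(self, g1_densities):
        g = tn.edge_weight_graph(g1_densities)
        assert g["A"]["B"]["weight"] == pytest.approx(2.0)
        assert g["A"]["C"]["weight"] == pytest.approx(5.0)

    def test_additive_synapse_factor(self, g1_densities):
        g = tn.edge_weight_graph(g1_densities, synapse_factor=1.0)
        assert g["A"]["B"]["weight"] == pytest.approx(3.0)

    def test_multiplicative_mode(self, g1_densities):
        g = tn.edge_weight_graph(g1_densities, synapse_factor=2.0, mode="multiplicative")
        assert g["A"]["B"]["weight"] == pytest.approx(4.0)

    def test_zero_density_absent_not_infinite(self, g1_densities):
        g = tn.edge_weight_graph(g1_densities)
        assert not g.has_edge("B", "A")
        assert all(math.isfinite(d["weight"]) and d["weight"] > 0 for _, _, d in g.edges(data=True))

    def test_self_loops_dropped(self):
        m = pd.DataFrame([[1.0, 0.5], [0.5, 1.0]], index=["a", "b"], columns=["a", "b"])
        g = tn.edge_weight_graph(m)
        assert not g.has_edge("a", "a")

    def test_invalid_arguments(self, g1_densities):
        with pytest.raises(ValueError):
            tn.edge_weight_graph(g1_densities, synapse_factor=-1)
        with pytest.raises(ValueError):
            tn.edge_weight_graph(g1_densities, mode="multiplicative")


class TestWorkedExampleTable:
    """Every metric on the fixed 4-node network vs. its hand-computed value."""

    def test_shortest_path_a_to_c_via_b(self, g1_graph):
        sp = tn.shortest_path(g1_graph, "A", "C")
        assert sp.nodes == ("A", "B", "C")
        assert sp.total_length == pytest.approx(4.0)
        assert sp.hops == 2

    def test_weighted_distance_a_to_d(self, g1_graph):
        dist = tn.all_pairs_weighted_distance(g1_graph)
        assert dist.loc["A", "D"] == pytest.approx(5.0)

    def test_source_equals_target(self, g1_graph):
        sp = tn.shortest_path(g1_graph, "A", "A")
        assert sp == tn.PathResult(("A",), 0.0, 0)

    def test_unreachable_marker(self, g1_graph):
        assert tn.shortest_path(g1_graph, "D", "A") is None

    def test_k_shortest_a_to_c(self, g1_graph):
        paths = tn.k_shortest_paths(g1_graph, "A", "C", k=2)
        assert [p.nodes for p in paths] == [("A", "B", "C"), ("A", "C")]
        assert [p.total_length for p in paths] == pytest.approx([4.0, 5.0])

    def test_betweenness_b_and_c(self, g1_graph):
        bc = tn.betweenness(g1_graph)
        assert bc["B"] == pytest.approx(1 / 3)
        assert bc["C"] == pytest.approx(1 / 3)
        assert bc["A"] == 0.0 and bc["D"] == 0.0

    def test_weighted_dos_by_synapse_factor(self, g1_densities):
        wd0 = tn.weighted_dos_matrix(tn.edge_weight_graph(g1_densities, synapse_factor=0))
        assert wd0.loc["A", "C"] == 2
        wd2 = tn.weighted_dos_matrix(tn.edge_weight_graph(g1_densities, synapse_factor=2))
        assert wd2.loc["A", "C"] == 1  # direct 5+2=7 beats 2+2+2+2=8

    def test_dos_threshold_sweep(self, g1_densities):
        assert tn.dos_matrix(tn.binarize(g1_densities, 0.0)).loc["A", "C"] == 1
        assert tn.dos_matrix(tn.binarize(g1_densities, 0.25)).loc["A", "C"] == 2


class TestPathAlgorithmsVsOracle:
    """Dijkstra/Yen/Brandes routes vs. exhaustive simple-path enumeration."""

    @pytest.mark.parametrize("seed", range(12))
    def test_all_metrics_agree(self, seed):
        dens = random_density_graph(seed)
        g = tn.edge_weight_graph(dens)
        nodes = sorted(g.nodes)
        dist = tn.all_pairs_weighted_distance(g)
        wdos = tn.weighted_dos_matrix(g)
        dos = tn.dos_matrix(tn.binarize(dens, 0.0))
        for s, t in itertools.permutations(nodes, 2):
            expect = oracle_shortest(g, s, t)
            got = tn.shortest_path(g, s, t)
            if expect is None:
                assert got is None
                assert math.isinf(dist.loc[s, t])
            else:
                assert got.nodes == expect[0]
                assert got.total_length == pytest.approx(expect[1], abs=1e-9)
                assert got.hops == expect[2]
                assert dist.loc[s, t] == pytest.approx(expect[1], abs=1e-9)
            assert wdos.loc[s, t] == oracle_weighted_dos(g, s, t)
            assert dos.loc[s, t] == oracle_dos(g, s, t)
            kex = oracle_k_shortest(g, s, t, 3)
            kgot = tn.k_shortest_paths(g, s, t, k=3)
            assert [p.nodes for p in kgot] == [i[0] for i in kex]
            assert [p.total_length for p in kgot] == pytest.approx([i[1] for i in kex])
        bc = tn.betweenness(g)
        for v, expect in oracle_betweenness(g).items():
            assert bc[v] == pytest.approx(expect, abs=1e-9)


class TestBetweennessShapes:
    def test_star_center_is_one(self):
        n = 6
        labels = [f"v{i}" for i in range(n)]
        m = pd.DataFrame(0.0, index=labels, columns=labels)
        for leaf in labels[1:]:
            m.loc["v0", leaf] = 1.0
            m.loc[leaf, "v0"] = 1.0
        bc = tn.betweenness(tn.edge_weight_graph(m))
        assert bc["v0"] == pytest.approx(1.0)
        assert all(bc[v] == 0.0 for v in labels[1:])

    def test_parallel_equal_routes_split_half(self):
        """Two co-minimal routes through v1 and v2 each accrue 1/2."""
        labels = ["s", "v1", "v2", "t"]
        m = pd.DataFrame(0.0, index=labels, columns=labels)
        for mid in ("v1", "v2"):
            m.loc["s", mid] = 0.5  # weight 2, exactly representable
            m.loc[mid, "t"] = 0.5
        bc = tn.betweenness(tn.edge_weight_graph(m))
        norm = (4 - 1) * (4 - 2)
        assert bc["v1"] == pytest.approx(0.5 / norm)
        assert bc["v2"] == pytest.approx(0.5 / norm)

    def test_unique_path_identity(self):
        """With unique shortest paths, raw BC sums to sum of (hops - 1)."""
        dens = random_density_graph(99)
        g = tn.edge_weight_graph(dens)
        n = g.number_of_nodes()
        bc = tn.betweenness(g)
        wdos = tn.weighted_dos_matrix(g)
        hops = wdos.to_numpy()
        finite = np.isfinite(hops) & (hops > 0)
        expect = (hops[finite] - 1).sum()
        assert bc.sum() * (n - 1) * (n - 2) == pytest.approx(expect, abs=1e-6)


class TestBinarizeAndDos:
    def test_strict_threshold_boundary(self):
        m = pd.DataFrame([[0.0, 0.76], [0.75, 0.0]], index=["a", "b"], columns=["a", "b"])
        out = tn.binarize(m, 0.75)
        assert out.loc["a", "b"] == 1.0
        assert out.loc["b", "a"] == 0.0
        assert tn.binarize(m, 0.75, strict=False).loc["b", "a"] == 1.0

    def test_zero_threshold_keeps_all_nonzero(self, g1_densities):
        out = tn.binarize(g1_densities, 0.0)
        assert out.to_numpy().sum() == 4

    def test_diagonal_forced_zero(self):
        m = pd.DataFrame([[1.0, 0.5], [0.5, 1.0]], index=["a", "b"], columns=["a", "b"])
        out = tn.binarize(m, 0.0)
        assert np.diag(out.to_numpy()).sum() == 0

    def test_edge_count_non_increasing_in_threshold(self, fixture_study):
        gt, _ = fixture_study
        counts = [
            tn.binarize(gt.matrix, t).values.sum() for t in (0, 0.25, 0.5, 0.75, 0.95)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_chain_dos(self):
        labels = ["a", "b", "c"]
        m = pd.DataFrame(0.0, index=labels, columns=labels)
        m.loc["a", "b"] = 1.0
        m.loc["b", "c"] = 1.0
        dos = tn.dos_matrix(m)
        assert dos.loc["a", "c"] == 2
        assert math.isinf(dos.loc["c", "a"])

    def test_dos_equals_weighted_distance_on_unit_weights(self):
        dens = random_density_graph(5)
        binary = tn.binarize(dens, 0.0)
        g_unit = nx.from_pandas_adjacency(binary, create_using=nx.DiGraph)
        g_unit.remove_edges_from(nx.selfloop_edges(g_unit))
        nx.set_edge_attributes(g_unit, 1.0, "weight")
        dist = tn.all_pairs_weighted_distance(g_unit)
        dos = tn.dos_matrix(binary)
        pd.testing.assert_frame_equal(dist, dos)

    def test_weighted_dos_at_least_dos(self):
        dens = random_density_graph(7)
        wdos = tn.weighted_dos_matrix(tn.edge_weight_graph(dens))
        dos = tn.dos_matrix(tn.binarize(dens, 0.0))
        assert (wdos.to_numpy() >= dos.to_numpy()).all()

    def test_dos_triangle_inequality(self):
        dens = random_density_graph(13)
        dos = tn.dos_matrix(tn.binarize(dens, 0.0))
        nodes = list(dos.index)
        for i, j, k in itertools.permutations(nodes, 3):
            if np.isfinite(dos.loc[i, j]) and np.isfinite(dos.loc[j, k]):
                assert dos.loc[i, k] <= dos.loc[i, j] + dos.loc[j, k]


class TestSynapseFactorLimit:
    def test_large_factor_minimizes_hops(self):
        """As s grows, weighted DOS converges to the binary DOS of the support."""
        for seed in range(5):
            dens = random_density_graph(seed, low=0.3)
            dos = tn.dos_matrix(tn.binarize(dens, 0.0))
            big = tn.weighted_dos_matrix(tn.edge_weight_graph(dens, synapse_factor=1000.0))
            pd.testing.assert_frame_equal(big, dos)


class TestWeightedDensity:
    def _matrix(self, small_tree):
        return tn.BilateralMatrix(
            values=np.array([[1.0, 0.5, 0.0, 0.2]]), source_nodes=(4,), nodes=(4, 5)
        )

    def test_density_times_distance(self, small_tree):
        out = tn.weighted_density(self._matrix(small_tree), small_tree)
        # nodes 4 and 5 are 5000 um apart; density 0.5 -> 2500
        assert out.values[0, 1] == pytest.approx(2500.0)

    def test_zero_density_stays_zero(self, small_tree):
        out = tn.weighted_density(self._matrix(small_tree), small_tree)
        assert out.values[0, 2] == 0.0

    def test_contra_uses_mirrored_distance(self, small_tree):
        out = tn.weighted_density(self._matrix(small_tree), small_tree)
        d = tn.centroid_distance(4, 5, False, small_tree)
        assert out.values[0, 3] == pytest.approx(0.2 * d)

    def test_linearity_in_coordinates(self):
        tree, nodes, grouping = tn.make_tree(6, seed=2)
        gt = tn.make_ground_truth(nodes, tree, grouping, seed=2)
        out1 = tn.weighted_density(gt.matrix, tree, midline=5700.0)
        doubled = tn.StructureTree(
            [
                tn.StructureRecord(
                    r.structure_id, r.acronym, r.name, r.parent_id,
                    None if r.centroid is None else tuple(2 * c for c in r.centroid),
                    r.volume,
                )
                for r in tree
            ]
        )
        out2 = tn.weighted_density(gt.matrix, doubled, midline=11400.0)
        np.testing.assert_allclose(out2.values, 2 * out1.values)

    def test_missing_centroid_raises(self):
        recs = [
            tn.StructureRecord(1, "R", "r", None, (0.0, 0.0, 0.0)),
            tn.StructureRecord(2, "A", "a", 1, None),
        ]
        tree = tn.StructureTree(recs)
        m = tn.BilateralMatrix(values=np.array([[1.0, 0.0]]), source_nodes=(2,), nodes=(2,))
        with pytest.raises(tn.MissingCentroidError):
            tn.weighted_density(m, tree)


class TestRelativeDensity:
    def test_basic_contrast(self):
        assert tn.relative_density(np.array([0.6]), np.array([0.2]))[0] == pytest.approx(0.5)

    def test_equal_inputs_zero(self):
        a = np.array([[0.3, 0.0], [0.5, 0.1]])
        np.testing.assert_array_equal(tn.relative_density(a, a.copy()), 0.0)

    def test_antisymmetry_and_range(self):
        rng = np.random.default_rng(4)
        a, b = rng.random((2, 6, 6))
        ab = tn.relative_density(a, b)
        np.testing.assert_allclose(ab, -tn.relative_density(b, a))
        assert (np.abs(ab) <= 1.0).all()

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="shape"):
            tn.relative_density(np.zeros((2, 2)), np.zeros((3, 3)))


class TestSummaries:
    def test_ipsi_mass_fraction_extremes(self):
        m = tn.BilateralMatrix(values=np.array([[1.0, 0.5, 0.0, 0.0]]),
                               source_nodes=(4,), nodes=(4, 5))
        assert tn.ipsi_mass_fraction(m) == 1.0

    def test_edge_density_full_ipsi(self):
        m = tn.BilateralMatrix(values=np.array([[1.0, 0.5, 0.0, 0.0]]),
                               source_nodes=(4,), nodes=(4, 5))
        # possible off-diagonal cells: 3, populated: 1
        assert tn.edge_density(m) == pytest.approx(1 / 3)

    def test_average_finite(self):
        df = pd.DataFrame([[0.0, 2.0], [np.inf, 0.0]], index=["a", "b"], columns=["a", "b"])
        mean, count = tn.average_finite(df)
        assert (mean, count) == (2.0, 1)
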