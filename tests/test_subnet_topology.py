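from __future__ import annotations

import itertools
import math

import networkx as nx
import numpy as np
import pytest
from scipy import stats as sps

from segnet.subnet_topology import (
    Subnetwork,
    betweenness,
    compare_strengths,
    connected_components,
    degree_centralization,
    density,
    exclusion_strength,
    extract_pair_subnetwork,
    largest_component_diameter,
    topology_report,
)
from segnet.network_model import AnnotatedEdge

from conftest import make_network
from oracles import (
    brute_betweenness,
    centralization_oracle,
    density_oracle,
    max_component_diameters,
    uf_components,
)


def _graph(edges):
    g = nx.Graph()
    g.add_edges_from(edges)
    return g


def _random_graph(rng: np.random.Generator) -> nx.Graph:
    n = int(rng.integers(2, 8))
    p = float(rng.uniform(0.15, 0.9))
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i, j in itertools.combinations(range(n), 2):
        if rng.random() < p:
            g.add_edge(i, j)
    return g


class TestExtraction:
    NET = [
        ("d1", "c1", 0.5),
        ("d1", "d2", 0.6),
        ("c1", "c2", 0.7),
    ]
    GROUPS = {"d1": "D", "d2": "D", "c1": "C", "c2": "C"}

    def test_hand_extraction(self):
        net = make_network(self.NET, self.GROUPS)
        sub = extract_pair_subnetwork(net, "D", "C")
        assert len(sub.edges) == 1
        assert sub.nodes == {"d1", "c1"}

    def test_sign_filter_can_empty(self):
        net = make_network(self.NET, self.GROUPS)
        sub = extract_pair_subnetwork(net, "D", "C", sign_filter="exclusion")
        assert sub.edges == []

    def test_symmetric_in_groups(self):
        net = make_network(self.NET, self.GROUPS)
        a = extract_pair_subnetwork(net, "D", "C")
        b = extract_pair_subnetwork(net, "C", "D")
        assert a.edges == b.edges

    def test_unknown_group_is_error(self):
        net = make_network(self.NET, self.GROUPS)
        with pytest.raises(KeyError):
            extract_pair_subnetwork(net, "D", "Z")


class TestComponents:
    def test_two_disjoint_edges(self):
        assert connected_components(_graph([("a", "b"), ("c", "d")])) == 2

    def test_path_plus_edge(self):
        assert connected_components(
            _graph([("a", "b"), ("b", "c"), ("d", "e")])
        ) == 2

    def test_empty_graph(self):
        assert connected_components(nx.Graph()) == 0

    def test_isolated_nodes_ignored(self):
        g = _graph([("a", "b")])
        g.add_node("z")
        assert connected_components(g) == 1


class TestDensity:
    def test_complete_graph(self):
        assert density(nx.complete_graph(4)) == 1.0

    def test_path_three_nodes(self):
        assert density(nx.path_graph(3)) == pytest.approx(2 / 3)

    def test_edgeless(self):
        g = nx.Graph()
        g.add_nodes_from(range(5))
        assert density(g) == 0.0

    def test_too_small_is_error(self):
        g = nx.Graph()
        g.add_node("a")
        with pytest.raises(ValueError, match=">= 2"):
            density(g)


class TestCentralization:
    def test_star_is_one(self):
        assert degree_centralization(nx.star_graph(3)) == pytest.approx(1.0)

    def test_cycle_is_zero(self):
        assert degree_centralization(nx.cycle_graph(5)) == 0.0

    def test_path_four_nodes(self):
        assert degree_centralization(nx.path_graph(4)) == pytest.approx(2 / 6)

    def test_too_small_is_error(self):
        with pytest.raises(ValueError, match=">= 3"):
            degree_centralization(nx.path_graph(2))


class TestBetweenness:
    def test_middle_of_path(self):
        bc = betweenness(nx.path_graph(["a", "b", "c"]))
        assert bc["b"] == pytest.approx(1.0)
        assert bc["a"] == bc["c"] == 0.0

    def test_star_center(self):
        bc = betweenness(nx.star_graph(4))
        assert bc[0] == pytest.approx(1.0)

    def test_values_in_unit_interval(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            g = _random_graph(rng)
            assert all(0.0 <= v <= 1.0 for v in betweenness(g).values())


class TestBruteForceOracles:
    """Criterion: metric agreement with naive oracles on 200 random graphs."""

    def test_random_graphs_agree_with_oracles(self):
        rng = np.random.default_rng(1234)
        for _ in range(200):
            g = _random_graph(rng)
            nodes = list(g.nodes)
            edges = list(g.edges)
            if edges:
                assert connected_components(g) == uf_components(nodes, edges)
                assert largest_component_diameter(g) in max_component_diameters(
                    nodes, edges
                )
            assert density(g) == pytest.approx(
                density_oracle(len(nodes), edges), abs=1e-12
            )
            if len(nodes) >= 3:
                assert degree_centralization(g) == pytest.approx(
                    centralization_oracle(nodes, edges), abs=1e-12
                )
            expected_bc = brute_betweenness(nodes, edges)
            got_bc = betweenness(g)
            for v in nodes:
                assert got_bc[v] == pytest.approx(expected_bc[v], abs=1e-9)

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(77)
        for _ in range(20):
            g = _random_graph(rng)
            if g.number_of_nodes() < 3:
                continue
            mapping = {n: f"x{n}" for n in g.nodes}
            h = nx.relabel_nodes(g, mapping)
            assert density(g) == pytest.approx(density(h))
            assert degree_centralization(g) == pytest.approx(
                degree_centralization(h)
            )

    def test_adding_edge_never_increases_components(self):
        rng = np.random.default_rng(99)
        for _ in range(50):
            g = _random_graph(rng)
            non_edges = list(nx.non_edges(g))
            if not non_edges:
                continue
            before = connected_components(g)
            u, v = non_edges[int(rng.integers(len(non_edges)))]
            g.add_edge(u, v)
            assert connected_components(g) <= before + 1
            # components over non-isolated nodes can rise by at most the
            # two endpoints joining as one fresh component
            assert connected_components(g) <= max(before + 1, 1)


class TestExclusionStrength:
    def _sub(self, scores):
        edges = [
            AnnotatedEdge(a=f"d{i}", b=f"c{i}", score=s)
            for i, s in enumerate(scores)
        ]
        return Subnetwork(focal_group="D", partner_group="C", edges=edges)

    def test_hand_computation(self):
        mean, sd = exclusion_strength(self._sub([-0.5, -0.7]))
        assert mean == pytest.approx(-0.6)
        assert sd == pytest.approx(math.sqrt(0.02), abs=1e-12)

    def test_single_score_warns_sd_zero(self):
        with pytest.warns(UserWarning, match="single exclusion"):
            mean, sd = exclusion_strength(self._sub([-0.66]))
        assert mean == pytest.approx(-0.66)
        assert sd == 0.0

    def test_no_exclusions_is_error(self):
        with pytest.raises(ValueError, match="no exclusion edges"):
            exclusion_strength(self._sub([0.5]))

    def test_truncated_normal_sample_mean(self):
        from segnet.synthetic_data import (
            GeneratorSpec, GroupSpec, PairParams, ScoreModel, generate_network,
        )

        spec = GeneratorSpec(
            groups=[GroupSpec("D", 40), GroupSpec("M", 40)],
            pair_params={("D", "M"): PairParams(800, 1.0)},
            score_model=ScoreModel(mu_exclusion=-0.66, sigma_exclusion=0.09),
            seed=3,
        )
        net, _ = generate_network(spec)
        sub = extract_pair_subnetwork(net, "D", "M")
        mean, _ = exclusion_strength(sub)
        assert abs(mean - (-0.66)) < 3 * 0.09 / math.sqrt(800)


class TestCompareStrengths:
    def test_identical_samples(self):
        t, df, p = compare_strengths([1, 2, 3, 4], [1, 2, 3, 4])
        assert t == 0.0
        assert p == pytest.approx(1.0)

    def test_textbook_welch_example(self):
        t, df, p = compare_strengths([1, 2, 3, 4], [2, 3, 4, 5])
        assert t == pytest.approx(-1.0954, abs=1e-4)
        assert df == pytest.approx(6.0)
        assert p == pytest.approx(0.315, abs=5e-3)

    def test_antisymmetry(self):
        x, y = [1.0, 2.5, 3.0], [2.0, 4.0, 4.5]
        t1, _, p1 = compare_strengths(x, y)
        t2, _, p2 = compare_strengths(y, x)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_matches_scipy_welch(self):
        rng = np.random.default_rng(8)
        for _ in range(25):
            x = rng.normal(size=int(rng.integers(3, 30)))
            y = rng.normal(loc=0.3, size=int(rng.integers(3, 30)))
            t, df, p = compare_strengths(x.tolist(), y.tolist())
            ref = sps.ttest_ind(x, y, equal_var=False)
            assert t == pytest.approx(ref.statistic, abs=1e-10)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_degenerate_variance_is_error(self):
        with pytest.raises(ValueError, match="zero variance"):
            compare_strengths([1.0, 1.0], [1.0, 1.0])

    def test_short_samples_are_error(self):
        with pytest.raises(ValueError, match=">= 2"):
            compare_strengths([1.0], [1.0, 2.0])


class TestTopologyReport:
    def _star_subnetwork(self):
        edges = [
            AnnotatedEdge(a="d1", b=f"c{i}", score=s)
            for i, s in enumerate([0.5, 0.6, -0.5])
        ]
        return Subnetwork(focal_group="D", partner_group="C", edges=edges)

    def test_star_hand_computation(self):
        rep = topology_report(self._star_subnetwork())
        assert rep.n_nodes == 4
        assert rep.n_edges == 3
        assert rep.density == pytest.approx(0.5)
        assert rep.centralization == pytest.approx(1.0)
        assert rep.diameter == 2
        assert rep.avg_neighbors == pytest.approx(1.5)
        assert rep.n_components == 1

    def test_sign_split_components(self):
        edges = [
            AnnotatedEdge(a="d1", b="c1", score=0.5),
            AnnotatedEdge(a="d2", b="c2", score=-0.5),
        ]
        rep = topology_report(Subnetwork("D", "C", edges))
        assert rep.n_components == 2
        assert rep.n_components_copresence == 1
        assert rep.n_components_exclusion == 1

    def test_empty_subnetwork_is_error(self):
        with pytest.raises(ValueError, match="empty"):
            topology_report(Subnetwork("D", "C", []))

    def test_internal_consistency_on_generated_subnetworks(self):
        from segnet.synthetic_data import (
            GeneratorSpec, GroupSpec, PairParams, generate_network,
        )

        for seed in range(5):
            spec = GeneratorSpec(
                groups=[GroupSpec("D", 12), GroupSpec("C", 15)],
                pair_params={("D", "C"): PairParams(30, 0.4)},
                seed=seed,
            )
            net, _ = generate_network(spec)
            sub = extract_pair_subnetwork(net, "D", "C")
            rep = topology_report(sub)
            n, m = rep.n_nodes, rep.n_edges
            assert rep.density == pytest.approx(m / (n * (n - 1) / 2))
            assert rep.avg_neighbors == pytest.approx(2 * m / n)
            assert all(0.0 <= v <= 1.0 for v in rep.betweenness.values())
            assert rep.n_components >= 1
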