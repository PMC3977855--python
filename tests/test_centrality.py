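import math

import numpy as np
import pytest

from cenval import (
    ConvergenceError,
    Graph,
    betweenness_centrality,
    closeness_centrality,
    compute_profile,
    degree_centrality,
    eccentricity_centrality,
    eigenvector_centrality,
)
from cenval.centrality import MEASURES

from .oracles import (
    brute_betweenness,
    brute_closeness,
    brute_eccentricity,
    dense_eigenvector,
)

SQRT2 = math.sqrt(2.0)


class TestClosedForms:
    """Analytic values on P3, K4, C4 and the K1,4 star."""

    def test_p3_degree(self, path3):
        assert degree_centrality(path3).scores == {"a": 0.5, "b": 1.0, "c": 0.5}

    def test_p3_betweenness(self, path3):
        assert betweenness_centrality(path3).scores == {"a": 0.0, "b": 1.0, "c": 0.0}

    def test_p3_closeness(self, path3):
        got = closeness_centrality(path3).scores
        assert got == pytest.approx({"a": 1 / 3, "b": 1 / 2, "c": 1 / 3})

    def test_p3_eccentricity(self, path3):
        assert eccentricity_centrality(path3).scores == {"a": 2, "b": 1, "c": 2}

    def test_p3_eigenvector(self, path3):
        res = eigenvector_centrality(path3)
        assert res.eigenvalue == pytest.approx(SQRT2, abs=1e-9)
        expected = np.array([1.0, SQRT2, 1.0])
        expected /= np.linalg.norm(expected)
        got = [res.vector.scores[v] for v in ("a", "b", "c")]
        assert got == pytest.approx(list(expected), abs=1e-9)

    def test_k4_all_measures(self, k4):
        assert set(degree_centrality(k4).scores.values()) == {1.0}
        assert set(betweenness_centrality(k4).scores.values()) == {0.0}
        assert list(closeness_centrality(k4).scores.values()) == pytest.approx([1 / 3] * 4)
        assert set(eccentricity_centrality(k4).scores.values()) == {1.0}
        res = eigenvector_centrality(k4)
        assert res.eigenvalue == pytest.approx(3.0, abs=1e-9)
        assert list(res.vector.scores.values()) == pytest.approx([0.5] * 4, abs=1e-9)

    def test_c4_constant_vectors(self, c4):
        assert list(degree_centrality(c4).scores.values()) == pytest.approx([2 / 3] * 4)
        assert list(betweenness_centrality(c4).scores.values()) == pytest.approx([0.5] * 4)
        assert list(closeness_centrality(c4).scores.values()) == pytest.approx([0.25] * 4)
        assert set(eccentricity_centrality(c4).scores.values()) == {2.0}
        res = eigenvector_centrality(c4)
        assert res.eigenvalue == pytest.approx(2.0, abs=1e-9)
        assert list(res.vector.scores.values()) == pytest.approx([0.5] * 4, abs=1e-9)

    def test_star_hub(self, star5):
        assert betweenness_centrality(star5).scores["h"] == pytest.approx(6.0)
        assert degree_centrality(star5).scores["h"] == 1.0
        res = eigenvector_centrality(star5)
        assert res.eigenvalue == pytest.approx(2.0, abs=1e-9)
        # hub entry 1/sqrt(2), leaves 1/sqrt(8)
        assert res.vector.scores["h"] == pytest.approx(1 / SQRT2, abs=1e-9)


class TestDegree:
    def test_sum_identity(self, random_graph):
        for seed in range(10):
            g = random_graph(20, 0.2, seed)
            total = sum(degree_centrality(g).scores.values()) * (g.n - 1)
            assert total == pytest.approx(2 * g.m)

    def test_raw_flag(self, path3):
        assert degree_centrality(path3, normalized=False).scores["b"] == 2

    def test_too_small(self):
        with pytest.raises(ValueError):
            degree_centrality(Graph(nodes=["a"]))


class TestBetweenness:
    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force(self, random_graph, seed):
        g = random_graph(9, 0.3, seed)
        got = betweenness_centrality(g).scores
        expected = brute_betweenness(g)
        for v in g.nodes:
            assert got[v] == pytest.approx(expected[v], abs=1e-9)

    def test_normalized_flag(self, star5):
        got = betweenness_centrality(star5, normalized=True).scores["h"]
        assert got == pytest.approx(1.0)  # 6 / C(4,2)

    def test_matches_networkx(self, karate):
        nx = pytest.importorskip("networkx")
        g = karate.graph
        ng = nx.Graph(g.edges)
        expected = nx.betweenness_centrality(ng, normalized=False)
        got = betweenness_centrality(g).scores
        for v in g.nodes:
            assert got[v] == pytest.approx(expected[v], abs=1e-8)


class TestClosenessEccentricity:
    @pytest.mark.parametrize("seed", range(8))
    def test_closeness_matches_oracle(self, random_connected_graph, seed):
        g = random_connected_graph(10, 0.4, seed)
        got = closeness_centrality(g).scores
        expected = brute_closeness(g)
        assert got == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("seed", range(8))
    def test_eccentricity_matches_oracle(self, random_connected_graph, seed):
        g = random_connected_graph(12, 0.3, seed)
        assert eccentricity_centrality(g).scores == brute_eccentricity(g)

    def test_radius_diameter_bounds(self, random_connected_graph):
        g = random_connected_graph(15, 0.25, 0)
        ecc = eccentricity_centrality(g).scores
        radius, diameter = min(ecc.values()), max(ecc.values())
        assert radius <= diameter <= 2 * radius
        assert all(radius <= e <= diameter for e in ecc.values())

    def test_disconnected_restricts_to_lcc(self):
        g = Graph(edges=[("a", "b"), ("b", "c")], nodes=["z"])
        vec = closeness_centrality(g)
        assert set(vec.scores) == {"a", "b", "c"}
        assert vec.restricted_to == frozenset({"a", "b", "c"})

    def test_singleton_component_error(self):
        with pytest.raises(ValueError, match="single node"):
            closeness_centrality(Graph(nodes=["a", "b"]))

    def test_freeman_variant(self, path3):
        got = closeness_centrality(path3, variant="freeman").scores
        assert got == pytest.approx({"a": 2 / 3, "b": 1.0, "c": 2 / 3})


class TestEigenvector:
    def test_needs_an_edge(self):
        with pytest.raises(ValueError):
            eigenvector_centrality(Graph(nodes=["a", "b"]))

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_dense_oracle(self, random_connected_graph, seed):
        g = random_connected_graph(10, 0.35, seed)
        lam, vec = dense_eigenvector(g)
        res = eigenvector_centrality(g)
        assert res.eigenvalue == pytest.approx(lam, abs=1e-8)
        for v in g.nodes:
            assert res.vector.scores[v] == pytest.approx(vec[v], abs=1e-7)

    def test_invariants(self, random_connected_graph):
        for seed in range(5):
            g = random_connected_graph(12, 0.3, seed)
            res = eigenvector_centrality(g)
            values = np.array(list(res.vector.scores.values()))
            assert (values >= 0).all()
            assert np.linalg.norm(values) == pytest.approx(1.0, abs=1e-9)
            assert res.residual <= 1e-10
            avg_deg = 2 * g.m / g.n
            max_deg = max(g.degree(v) for v in g.nodes)
            assert avg_deg - 1e-9 <= res.eigenvalue <= max_deg + 1e-9

    def test_bipartite_resolved_by_shift(self):
        # P2 from a lopsided start is fine, but K3,3 minus a perfect matching
        # style graphs can oscillate; a plain 6-cycle exercises the shift path
        # only if the plain run fails, so assert the contract rather than the
        # mechanism: result converges and matches the dense oracle.
        g = Graph(edges=[("a", "b"), ("b", "c"), ("c", "d"), ("d", "e"), ("e", "f"), ("a", "f")])
        res = eigenvector_centrality(g)
        lam, _ = dense_eigenvector(g)
        assert res.eigenvalue == pytest.approx(lam, abs=1e-8)

    def test_nonconvergence_raises_with_residual(self, path3):
        with pytest.raises(ConvergenceError) as exc_info:
            eigenvector_centrality(path3, tol=1e-16, max_iter=3)
        assert exc_info.value.residual > 0


class TestProfile:
    def test_karate_degree_argmin_unique(self, karate):
        profile = compute_profile(karate.graph, "karate")
        scores = profile["degree"].scores
        mn = min(scores.values())
        assert sum(1 for s in scores.values() if s == mn) == 1

    def test_has_all_measures(self, path3):
        profile = compute_profile(path3)
        assert set(profile.vectors) == set(MEASURES)

    def test_restriction_recorded(self):
        g = Graph(edges=[("a", "b"), ("b", "c")], nodes=["z"])
        profile = compute_profile(g)
        assert any("largest connected component" in w for w in profile.warnings)
        assert profile["closeness"].restricted_to is not None
        assert set(profile["degree"].scores) == set(g.nodes)

    def test_isomorphism_equivariance(self, random_connected_graph):
        g = random_connected_graph(12, 0.3, 7)
        mapping = {v: f"x{i}" for i, v in enumerate(reversed(g.nodes))}
        h = Graph(edges=[(mapping[u], mapping[v]) for u, v in g.edges])
        pg, ph = compute_profile(g), compute_profile(h)
        for m in MEASURES:
            for v in g.nodes:
                assert pg[m].scores[v] == pytest.approx(
                    ph[m].scores[mapping[v]], abs=1e-8
                )

    def test_vertex_transitive_constant(self):
        c7 = Graph(edges=[(str(i), str((i + 1) % 7)) for i in range(7)])
        profile = compute_profile(c7)
        for m in MEASURES:
            values = list(profile[m].scores.values())
            assert max(values) - min(values) < 1e-9
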