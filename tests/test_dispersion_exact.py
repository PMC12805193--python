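import numpy as np
import pytest

from anticlustering import (
    CannotLinkGraph,
    InfeasibleConstraintsError,
    Partition,
    build_cannot_link_graph,
    brute_force_oracle,
    complete_partition,
    dispersion,
    k_color_with_cardinalities,
    optimal_dispersion,
    satisfy_cannot_link,
)
from anticlustering.dispersion_exact import _color_ilp, _feasible_coloring
from conftest import random_instance


class TestCannotLinkGraph:
    def test_edges_at_thresholds(self, d4):
        assert build_cannot_link_graph(d4, 1.0).edges == {(0, 1)}
        assert build_cannot_link_graph(d4, 2.0).edges == {(0, 1), (0, 2)}
        assert build_cannot_link_graph(d4, 0.5).edges == frozenset()

    def test_rejects_self_loop(self):
        with pytest.raises(ValueError):
            CannotLinkGraph(3, frozenset({(1, 1)}))


class TestBoundedColoring:
    def test_feasible_at_theta_two(self, d4):
        G = build_cannot_link_graph(d4, 2.0)
        coloring = k_color_with_cardinalities(G, 2, [2, 2])
        assert coloring is not None
        assert sorted(np.bincount(coloring)) == [2, 2]
        for u, v in G.edges:
            assert coloring[u] != coloring[v]

    def test_cardinalities_make_theta_three_infeasible(self, d4):
        # star around object 1 is 2-colorable, but not with groups of 2
        G = build_cannot_link_graph(d4, 3.0)
        assert k_color_with_cardinalities(G, 2, [2, 2]) is None
        assert _feasible_coloring(G, 2, None) is not None

    def test_empty_graph_feasible(self):
        G = CannotLinkGraph(6, frozenset())
        coloring = k_color_with_cardinalities(G, 3, [2, 2, 2])
        assert sorted(np.bincount(coloring)) == [2, 2, 2]

    @pytest.mark.parametrize("K,sizes", [(2, (3, 3)), (3, (2, 2, 2)), (3, (1, 2, 3))])
    def test_polynomial_and_greedy_routes_agree_with_ilp(self, rng, K, sizes):
        """Feasibility verdicts of the fast paths match the ILP on random graphs."""
        for _ in range(30):
            n_edges = int(rng.integers(0, 13))
            edges = set()
            while len(edges) < n_edges:
                u, v = rng.integers(0, 6, size=2)
                if u != v:
                    edges.add((min(u, v), max(u, v)))
            G = CannotLinkGraph(6, frozenset(edges))
            fast = _feasible_coloring(G, K, list(sizes))
            constrained = [v for v in range(6) if G.adjacency()[v]]
            ilp = _color_ilp(constrained, G.edges, K, list(sizes), None)
            assert (fast is None) == (ilp is None)
            if fast is not None:
                counts = np.bincount(list(fast.values()), minlength=K)
                assert (counts <= np.asarray(sizes)).all()
                for u, v in edges:
                    if u in fast and v in fast:
                        assert fast[u] != fast[v]


class TestOptimalDispersion:
    def test_toy_with_cardinalities(self, d4):
        res = optimal_dispersion(d4, 2, [2, 2])
        assert res.dispersion == 3.0
        assert res.theta_star == 2.0

    def test_toy_without_cardinalities(self, d4):
        res = optimal_dispersion(d4, 2, None)
        assert res.dispersion == 4.0

    def test_two_objects_sentinel(self):
        D = np.array([[0.0, 5.0], [5.0, 0.0]])
        res = optimal_dispersion(D, 2, [1, 1])
        assert res.dispersion == np.inf

    def test_binary_and_linear_sweeps_agree(self, rng):
        for _ in range(15):
            N = int(rng.choice([6, 8, 10]))
            _, D = random_instance(rng, N)
            K = int(rng.choice([2, 3]))
            if N % K:
                K = 2
            sizes = [N // K] * K
            a = optimal_dispersion(D, K, sizes, strategy="binary")
            b = optimal_dispersion(D, K, sizes, strategy="linear")
            assert a.dispersion == b.dispersion
            assert a.theta_star == b.theta_star

    def test_matches_brute_force(self, rng):
        for _ in range(25):
            K = int(rng.choice([2, 3]))
            N = int(rng.choice([4, 6, 8, 10] if K == 2 else [6, 9]))
            _, D = random_instance(rng, N)
            sizes = [N // K] * K
            res = optimal_dispersion(D, K, sizes)
            _, best_disp, _ = brute_force_oracle(D, K, sizes)
            assert res.dispersion == pytest.approx(best_disp, rel=1e-12)

    def test_tie_invariance_to_input_order(self):
        # several tied distances processed as one grid step
        D = np.array(
            [
                [0.0, 1.0, 1.0, 2.0],
                [1.0, 0.0, 2.0, 1.0],
                [1.0, 2.0, 0.0, 1.0],
                [2.0, 1.0, 1.0, 0.0],
            ]
        )
        res = optimal_dispersion(D, 2, [2, 2])
        perm = np.array([3, 1, 0, 2])
        res_p = optimal_dispersion(D[np.ix_(perm, perm)], 2, [2, 2])
        assert res.dispersion == res_p.dispersion

    def test_partial_assignment_certifies_value(self, d4, rng):
        res = optimal_dispersion(d4, 2, [2, 2])
        part = complete_partition(res, rng)
        assert part == Partition(np.array([0, 1, 1, 0]))
        assert dispersion(d4, part) == res.dispersion


class TestCompletePartition:
    def test_completion_always_attains_optimum(self, rng):
        for _ in range(15):
            N = int(rng.choice([8, 10, 12]))
            _, D = random_instance(rng, N)
            res = optimal_dispersion(D, 2, [N // 2] * 2)
            for _ in range(7):
                part = complete_partition(res, rng)
                assert list(np.bincount(part.assignment)) == [N // 2] * 2
                assert dispersion(D, part) == pytest.approx(res.dispersion, rel=1e-12)

    def test_forced_completion_is_deterministic(self, d4, rng):
        # at theta* = 2 only one free slot remains, so every completion
        # yields the unique dispersion-optimal partition {14|23}
        res = optimal_dispersion(d4, 2, [2, 2])
        p1 = complete_partition(res, rng)
        p2 = complete_partition(res, rng)
        assert p1 == p2 == Partition(np.array([0, 1, 1, 0]))


class TestSatisfyCannotLink:
    def test_single_pair_separated(self, rng):
        part = satisfy_cannot_link([(0, 1)], 4, 2, [2, 2], rng)
        assert part.assignment[0] != part.assignment[1]

    def test_pigeonhole_infeasible(self, rng):
        with pytest.raises(InfeasibleConstraintsError):
            satisfy_cannot_link([(0, 1), (0, 2), (0, 3)], 4, 2, [2, 2], rng)

    def test_no_constraints_feasible(self, rng):
        part = satisfy_cannot_link([], 6, 3, [2, 2, 2], rng)
        assert sorted(part.sizes.tolist()) == [2, 2, 2]
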