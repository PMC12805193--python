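import numpy as np
import pytest

from anticlustering import (
    BilsConfig,
    ParetoSet,
    Partition,
    bils,
    bpi,
    brute_force_oracle,
    complete_partition,
    dispersion,
    diversity,
    ils_perturb,
    lcw,
    mbpi,
    optimal_dispersion,
    random_partition,
    restricted_lcw,
    select_entry,
)
from conftest import random_instance, reference_bpi


class TestBpiKernel:
    """The jitted kernel against a from-scratch pure-Python reference."""

    @pytest.mark.parametrize("w", [1.0, 0.999, 0.5, 0.001])
    @pytest.mark.parametrize("use_avg", [False, True])
    def test_trajectory_matches_reference(self, rng, w, use_avg):
        for _ in range(6):
            N = int(rng.choice([6, 8, 10]))
            _, D = random_instance(rng, N)
            init = random_partition(N, [N // 2] * 2, rng)
            crit = "average-diversity" if use_avg else "diversity"
            final, _ = bpi(D, D, w, init, criterion=crit)
            ref_assign, _ = reference_bpi(
                D, D, w, init.assignment, 2, use_avg=use_avg
            )
            assert np.array_equal(final.assignment, ref_assign)

    def test_output_is_two_swap_local_optimum(self, rng):
        """No single pairwise exchange improves the final diversity."""
        for _ in range(5):
            N = 10
            _, D = random_instance(rng, N)
            init = random_partition(N, [5, 5], rng)
            final = lcw(D, init)
            base = diversity(D, final)
            assert base >= diversity(D, init) - 1e-12
            for i in range(N):
                for j in range(N):
                    if final.assignment[i] != final.assignment[j]:
                        trial = final.assignment.copy()
                        trial[i], trial[j] = trial[j], trial[i]
                        assert diversity(D, Partition(trial, K=2)) <= base + 1e-7 * (1 + base)

    def test_equal_sizes_average_diversity_same_trajectory(self, rng):
        """With equal sizes the average-diversity criterion is a positive
        rescaling of diversity, so the accepted-swap trajectory is identical."""
        for _ in range(5):
            N = 12
            _, D = random_instance(rng, N)
            init = random_partition(N, [4, 4, 4], rng)
            f1, _ = bpi(D, D, 1.0, init, criterion="diversity")
            f2, _ = bpi(D, D, 1.0, init, criterion="average-diversity")
            assert f1 == f2

    def test_pareto_set_stays_nondominated(self, d4, rng):
        S = ParetoSet()
        init = Partition(np.array([0, 0, 1, 1]))
        bpi(d4, d4, 0.5, init, S)
        assert (7.0, 3.0) in S.score_pairs()
        entries = list(S)
        from anticlustering import dominates

        for a in entries:
            for b in entries:
                if a is not b:
                    assert not dominates(a, b)


class TestLcw:
    def test_local_optimum_returned_unchanged(self, d4):
        init = Partition(np.array([0, 1, 1, 0]))
        assert lcw(d4, init) == init

    def test_toy_reaches_maximum_diversity(self, d4):
        final = lcw(d4, Partition(np.array([0, 0, 1, 1])))
        assert diversity(d4, final) == pytest.approx(7.0)


class TestRestrictedLcw:
    def test_toy(self, d4, rng):
        res = optimal_dispersion(d4, 2, [2, 2])
        entry = restricted_lcw(d4, d4, res, rng)
        assert entry.scores == (7.0, 3.0)
        assert entry.partition == Partition(np.array([0, 1, 1, 0]))

    def test_dispersion_always_optimal(self, rng):
        for _ in range(20):
            N = int(rng.choice([10, 14, 20]))
            _, D = random_instance(rng, N, P=3)
            K = 2
            res = optimal_dispersion(D, K, [N // K] * K)
            entry = restricted_lcw(D, D, res, rng)
            assert entry.dispersion == pytest.approx(res.dispersion, rel=1e-12)
            assert dispersion(D, entry.partition) == pytest.approx(
                res.dispersion, rel=1e-12
            )


class TestMbpi:
    def test_single_restart_equals_bpi(self, d4):
        rng1 = np.random.default_rng(3)
        S1 = mbpi(d4, d4, 2, [2, 2], 1, rng1)
        rng2 = np.random.default_rng(3)
        w = float(rng2.choice((0.000001, 0.00001, 0.0001, 0.001, 0.01, 0.1, 0.5, 0.99, 0.999, 0.999999)))
        init = random_partition(4, [2, 2], rng2)
        _, S2 = bpi(d4, d4, w, init)
        assert S1.score_pairs() == S2.score_pairs()

    def test_deterministic_under_seed(self, rng):
        _, D = random_instance(rng, 10)
        S1 = mbpi(D, D, 2, [5, 5], 8, np.random.default_rng(7))
        S2 = mbpi(D, D, 2, [5, 5], 8, np.random.default_rng(7))
        assert [e.partition.canonical() for e in S1] == [
            e.partition.canonical() for e in S2
        ]

    def test_toy_finds_frontier(self, d4):
        S = mbpi(d4, d4, 2, [2, 2], 10, np.random.default_rng(0))
        assert S.score_pairs() == {(7.0, 3.0)}


class TestIlsPerturb:
    def test_preserves_cardinalities(self, rng):
        for _ in range(200):
            sizes = [4, 3, 3]
            part = random_partition(10, sizes, rng)
            out = ils_perturb(part, 0.08, rng)
            assert np.array_equal(np.bincount(out.assignment), np.bincount(part.assignment))

    def test_swap_rate_matches_probability(self):
        """Exactly p of the eligible (cross-cluster) pair visits swap, on
        average; verified by replaying the pre-drawn uniform stream."""
        N, p = 60, 0.05
        eligible_total = 0
        swapped_total = 0
        for seed in range(250):
            rng = np.random.default_rng(seed)
            part = random_partition(N, [30, 30], rng)
            replay_rng = np.random.default_rng(seed)
            random_partition(N, [30, 30], replay_rng)  # align streams
            out = ils_perturb(part, p, rng)
            uniforms = replay_rng.random(N * (N - 1) // 2)
            assign = part.assignment.copy()
            t = 0
            for i in range(N):
                for j in range(i + 1, N):
                    u = uniforms[t]
                    t += 1
                    if assign[i] != assign[j]:
                        eligible_total += 1
                        if u < p:
                            swapped_total += 1
                            assign[i], assign[j] = assign[j], assign[i]
            assert np.array_equal(assign, out.assignment)
        rate = swapped_total / eligible_total
        se = np.sqrt(p * (1 - p) / eligible_total)
        assert abs(rate - p) < 4 * se

    def test_rejects_bad_probability(self, rng):
        part = random_partition(6, [3, 3], rng)
        with pytest.raises(ValueError):
            ils_perturb(part, 0.0, rng)


class TestBils:
    def test_toy_all_modes(self, d4):
        for mode in ("vanilla", "hybrid-1", "hybrid-all"):
            S = bils(
                d4,
                K=2,
                sizes=[2, 2],
                cfg=BilsConfig(restarts_total=10, init_mode=mode),
                rng=np.random.default_rng(5),
            )
            assert S.score_pairs() == {(7.0, 3.0)}

    def test_deterministic_under_seed(self, rng):
        _, D = random_instance(rng, 12)
        cfg = BilsConfig(restarts_total=12, init_mode="hybrid-all")
        S1 = bils(D, K=2, sizes=[6, 6], cfg=cfg, rng=np.random.default_rng(11))
        S2 = bils(D, K=2, sizes=[6, 6], cfg=cfg, rng=np.random.default_rng(11))
        assert [e.partition.canonical() for e in S1] == [
            e.partition.canonical() for e in S2
        ]

    def test_hybrid_guarantees_optimal_dispersion(self, rng):
        for _ in range(10):
            N = int(rng.choice([12, 16, 20]))
            _, D = random_instance(rng, N, P=3)
            res = optimal_dispersion(D, 2, [N // 2] * 2)
            for mode in ("hybrid-1", "hybrid-all"):
                S = bils(
                    D,
                    K=2,
                    sizes=[N // 2] * 2,
                    cfg=BilsConfig(restarts_total=6, init_mode=mode),
                    rng=rng,
                    disp_result=res,
                )
                best = select_entry(S, "max-dispersion")
                assert best.dispersion == pytest.approx(res.dispersion, rel=1e-12)

    def test_small_instances_recover_exact_frontier(self, rng):
        hits = 0
        trials = 20
        for _ in range(trials):
            K = int(rng.choice([2, 3]))
            N = 8 if K == 2 else 9
            _, D = random_instance(rng, N)
            sizes = [N // K] * K
            S = bils(
                D,
                K=K,
                sizes=sizes,
                cfg=BilsConfig(restarts_total=100, init_mode="hybrid-all"),
                rng=rng,
            )
            _, _, oracle = brute_force_oracle(D, K, sizes)
            want = oracle.score_pairs()
            got = S.score_pairs()
            # heuristic set is always a subset of the true frontier
            for g in got:
                assert any(
                    g[0] == pytest.approx(wv[0], rel=1e-9)
                    and g[1] == pytest.approx(wv[1], rel=1e-9)
                    for wv in want
                )
            if len(got) == len(want):
                hits += 1
        assert hits >= 0.95 * trials - 1e-9

    def test_cardinalities_preserved_in_every_entry(self, rng):
        _, D = random_instance(rng, 12)
        S = bils(
            D,
            K=3,
            sizes=[4, 4, 4],
            cfg=BilsConfig(restarts_total=10, init_mode="vanilla"),
            rng=rng,
        )
        for e in S:
            assert sorted(np.bincount(e.partition.assignment).tolist()) == [4, 4, 4]


class TestSelectEntry:
    def test_rules(self, d4):
        S = ParetoSet()
        from anticlustering import ParetoEntry

        S.add(ParetoEntry(Partition(np.array([0, 0, 1, 1])), 10.0, 1.0))
        S.add(ParetoEntry(Partition(np.array([0, 1, 0, 1])), 8.0, 2.0))
        assert select_entry(S, "max-dispersion").scores == (8.0, 2.0)
        assert select_entry(S, "max-diversity").scores == (10.0, 1.0)
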