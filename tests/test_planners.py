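import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gridplan.gridworld import generate_problem
from gridplan.planners import (
    PlanCache,
    PlannerConfig,
    PlannerError,
    classify_min_depth,
    dead_end_gems,
    enumerate_partial_paths,
    filter_obvious_ending,
    rollout,
    rollout_pmf,
    select_plan,
)
from conftest import full_grid_problem
from _oracles import iter_k_gem_paths, oracle_min_depth, shortest_k_gem_paths


class TestPlannerConfig:
    def test_epsilon_requires_matching_variant(self):
        with pytest.raises(PlannerError):
            PlannerConfig(depth=1, epsilon=0.1)
        with pytest.raises(PlannerError):
            PlannerConfig(depth=1, variant="epsilon_greedy")

    def test_depth_bounds(self):
        with pytest.raises(PlannerError):
            PlannerConfig(depth=9)


class TestEnumeratePartialPaths:
    def test_toy_unique_shortest_one_gem(self, p_toy):
        cands = enumerate_partial_paths(p_toy, (0, 0), {(0, 0)}, 1, shortest_only=True)
        assert [c.nodes for c in cands] == [((0, 0), (1, 0), (2, 0))]

    def test_adjacent_gem_gives_length_one_path(self):
        p = full_grid_problem(3, 3, (0, 0), [(0, 1)])
        cands = enumerate_partial_paths(p, (0, 0), {(0, 0)}, 1)
        assert ((0, 0), (0, 1)) in {c.nodes for c in cands}

    def test_impossible_demand_is_empty(self, p_toy):
        assert enumerate_partial_paths(p_toy, (0, 0), {(0, 0)}, 3) == ()

    def test_paths_end_at_kth_gem(self, small_problems):
        for p in small_problems[:4]:
            for k in (1, 2):
                for c in enumerate_partial_paths(p, p.home, {p.home}, k):
                    gems_on = [n for n in c.nodes if n in p.gems]
                    assert len(gems_on) == k
                    assert c.nodes[-1] == gems_on[-1]

    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_full_enumeration_matches_oracle(self, small_problems, k):
        for p in small_problems[:3]:
            ours = {c.nodes for c in enumerate_partial_paths(p, p.home, {p.home}, k)}
            assert ours == set(iter_k_gem_paths(p, p.home, {p.home}, k))

    def test_shortest_matches_oracle_mid_episode(self, small_problems):
        for p in small_problems:
            start = next(iter(sorted(p.gems)))
            visited = {p.home, start}
            ours = {c.nodes for c in enumerate_partial_paths(
                p, start, visited, 1, shortest_only=True)}
            assert ours == shortest_k_gem_paths(p, start, visited, 1)

    def test_cache_round_trip(self, p_toy):
        cache = PlanCache()
        a = enumerate_partial_paths(p_toy, (0, 0), {(0, 0)}, 2, shortest_only=True, cache=cache)
        b = enumerate_partial_paths(p_toy, (0, 0), {(0, 0)}, 2, shortest_only=True, cache=cache)
        assert a == b and len(cache) == 1


class TestSelectPlan:
    def _paths(self, p_toy, k):
        return enumerate_partial_paths(p_toy, (0, 0), {(0, 0)}, k)

    def test_strict_argmin(self, p_toy):
        cands = self._paths(p_toy, 1)  # lengths 2 and 4+
        rng = np.random.default_rng(0)
        for _ in range(20):
            assert select_plan(cands, PlannerConfig(depth=1), rng).length == 2

    def test_tie_break_uniform(self):
        p = full_grid_problem(3, 3, (0, 0), [(1, 1)])
        cands = enumerate_partial_paths(p, (0, 0), {(0, 0)}, 1, shortest_only=True)
        assert len(cands) == 2  # via (0,1) or (1,0)
        rng = np.random.default_rng(5)
        n = 4000
        hits = sum(select_plan(cands, PlannerConfig(depth=1), rng) == cands[0]
                   for _ in range(n))
        se = np.sqrt(0.25 / n)
        assert abs(hits / n - 0.5) < 3 * se

    def test_softmax_beta_zero_is_uniform(self, p_toy):
        cands = self._paths(p_toy, 1)[:3]
        cfg = PlannerConfig(depth=1, variant="softmax", beta=0.0)
        rng = np.random.default_rng(11)
        n = 6000
        counts = np.zeros(len(cands))
        for _ in range(n):
            counts[cands.index(select_plan(cands, cfg, rng))] += 1
        se = np.sqrt((1 / 3) * (2 / 3) / n)
        assert np.abs(counts / n - 1 / 3).max() < 3 * se

    def test_high_beta_softmax_matches_argmin(self, p_toy):
        """beta >= 50 on integer lengths is argmin in >= 99.9% of draws."""
        cands = self._paths(p_toy, 1)
        best = min(c.length for c in cands)
        cfg = PlannerConfig(depth=1, variant="softmax", beta=50.0)
        rng = np.random.default_rng(13)
        agree = sum(select_plan(cands, cfg, rng).length == best for _ in range(3000))
        assert agree / 3000 >= 0.999

    def test_empty_candidates_rejected(self):
        with pytest.raises(PlannerError):
            select_plan([], PlannerConfig(depth=1), np.random.default_rng(0))


class TestObviousEnding:
    def test_toy_dead_end_gem_must_be_last(self, p_toy):
        assert dead_end_gems(p_toy, p_toy.gems) == {(2, 0)}
        cands = enumerate_partial_paths(p_toy, (0, 0), {(0, 0)}, 2)
        kept = filter_obvious_ending(p_toy, cands, p_toy.gems, {(0, 0)})
        assert kept and all(c.nodes[-1] == (2, 0) for c in kept)

    def test_no_dead_end_gems_passes_through(self):
        p = full_grid_problem(3, 3, (0, 0), [(0, 2), (2, 2)])
        cands = enumerate_partial_paths(p, (0, 0), {(0, 0)}, 1, shortest_only=True)
        assert filter_obvious_ending(p, cands, p.gems, {(0, 0)}) == tuple(cands)

    def test_all_candidates_violating_gives_empty(self, p_toy):
        # non-final plans through the dead-end gem are all rejected
        cands = enumerate_partial_paths(p_toy, (0, 0), {(0, 0)}, 1, shortest_only=True)
        assert all((2, 0) in c.nodes for c in cands)
        assert filter_obvious_ending(p_toy, cands, p_toy.gems, {(0, 0)}) == ()


class TestRollout:
    def test_toy_depth1_strands_after_one_gem(self, p_toy):
        for seed in range(5):
            out = rollout(p_toy, PlannerConfig(depth=1), np.random.default_rng(seed))
            assert (out.gems_collected, out.termination) == (1, "dead_end")
            assert not out.solved

    def test_toy_depth2_always_solves(self, p_toy):
        for seed in range(5):
            out = rollout(p_toy, PlannerConfig(depth=2), np.random.default_rng(seed))
            assert out.solved and out.gems_collected == 2
            assert out.trajectory.length == 8

    def test_full_depth_solution_is_minimum_length(self, small_problems):
        for p in small_problems[:4]:
            shortest = enumerate_partial_paths(
                p, p.home, {p.home}, p.num_gems, shortest_only=True)
            out = rollout(p, PlannerConfig(depth=8), np.random.default_rng(3))
            if out.solved:
                assert out.trajectory.length == shortest[0].length

    def test_epsilon_zero_identical_to_base(self, small_problems):
        eps0 = PlannerConfig(depth=2, variant="epsilon_greedy", epsilon=0.0)
        base = PlannerConfig(depth=2)
        for p in small_problems:
            for seed in range(4):
                a = rollout(p, eps0, np.random.default_rng(seed))
                b = rollout(p, base, np.random.default_rng(seed))
                assert a.trajectory == b.trajectory

    def test_trajectory_always_simple_and_legal(self, small_problems):
        configs = [
            PlannerConfig(depth=1),
            PlannerConfig(depth=3, variant="epsilon_greedy", epsilon=0.3),
            PlannerConfig(depth=2, variant="softmax", beta=1.0),
            PlannerConfig(depth=2, variant="obvious_ending"),
        ]
        for p in small_problems:
            for cfg in configs:
                out = rollout(p, cfg, np.random.default_rng(17))
                out.trajectory.validate_on(p)  # raises on repeat or non-edge
                assert out.trajectory.nodes[0] == p.home


class TestRolloutPMF:
    def test_toy_concentrates(self, p_toy):
        p1 = rollout_pmf(p_toy, PlannerConfig(depth=1, seed=1), R=100)
        p2 = rollout_pmf(p_toy, PlannerConfig(depth=2, seed=1), R=100)
        assert p1.probabilities == (0.0, 1.0, 0.0)
        assert p2.probabilities == (0.0, 0.0, 1.0)

    def test_single_instance_degenerate(self, p_toy):
        pmf = rollout_pmf(p_toy, PlannerConfig(depth=1, seed=0), R=1)
        assert sorted(pmf.probabilities) == [0.0, 0.0, 1.0]

    def test_support_and_normalization(self, small_problems):
        p = small_problems[0]
        cfg = PlannerConfig(depth=2, variant="epsilon_greedy", epsilon=0.2, seed=9)
        pmf = rollout_pmf(p, cfg, R=200)
        assert pmf.support_size == p.num_gems + 1
        assert abs(sum(pmf.probabilities) - 1.0) < 1e-12


class TestClassifyMinDepth:
    def test_toy_is_depth_two(self, p_toy):
        assert classify_min_depth(p_toy) == 2

    def test_full_lattice_single_gem_is_greedy(self):
        p = full_grid_problem(4, 4, (0, 0), [(3, 3)])
        assert classify_min_depth(p) == 1

    def test_matches_brute_force_oracle(self, small_problems):
        for p in small_problems:
            assert classify_min_depth(p) == oracle_min_depth(p)


@given(seed=st.integers(0, 2**20), depth=st.integers(1, 4))
@settings(max_examples=20, deadline=None, derandomize=True)
def test_rollout_of_random_problem_is_simple_path(seed, depth):
    p = generate_problem(4, 4, 3, 0.75, np.random.default_rng(seed))
    out = rollout(p, PlannerConfig(depth=depth), np.random.default_rng(seed + 1))
    out.trajectory.validate_on(p)
    assert out.gems_collected == sum(1 for n in out.trajectory.nodes if n in p.gems)
    assert out.solved == (out.gems_collected == p.num_gems)
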