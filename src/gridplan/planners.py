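"""Depth-limited forward planners and minimum-depth classification.

The depth-``n`` planner repeatedly enumerates every simple partial path from
its current position that collects exactly ``k = min(n, remaining gems)``
uncollected gems, ending on the ``k``-th, and commits to the shortest one
(uniformly at random among ties). Crossed nodes become off-limits, so a bad
commitment can strand the agent in a dead end; planners never backtrack, and
a stranded episode simply ends. Four variants share this skeleton:

``base``
    argmin path selection with uniform tie-breaking.
``obvious_ending``
    additionally discards plans in which a gem sitting in a dead end (or
    connected only to dead ends) is not collected last.
``epsilon_greedy``
    while executing a plan, each single-node step is replaced with
    probability ``epsilon`` by a uniformly random legal move, after which
    the agent replans from the new position.
``softmax``
    samples among candidate paths with probability proportional to
    ``exp(-beta * length)`` instead of taking the argmin.

The minimum required depth of a problem is the smallest ``n`` at which the
base depth-``n`` planner solves it with non-zero probability; it is computed
by exact enumeration of the planner's stochastic branch tree (branching at
shortest-path ties) with memoization, falling back to Monte Carlo when the
tree is too large.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .gridworld import GridProblem, GridworldError, Node, Path, legal_moves

UNCLASSIFIABLE = "unclassifiable"

#: default number of planner instances per (problem, depth) when building
#: empirical outcome distributions
DEFAULT_INSTANCES = 500

#: softmax candidate enumeration keeps paths at most this many edges longer
#: than the shortest candidate (tail weight <= exp(-beta * window))
SOFTMAX_LENGTH_WINDOW = 6

VARIANTS = ("base", "obvious_ending", "epsilon_greedy", "softmax")


class PlannerError(GridworldError):
    pass


@dataclass(frozen=True)
class PlannerConfig:
    """One member of the planner family."""

    depth: int
    variant: str = "base"
    epsilon: Optional[float] = None
    beta: Optional[float] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.depth <= 8:
            raise PlannerError(f"depth must be 1..8, got {self.depth}")
        if self.variant not in VARIANTS:
            raise PlannerError(f"unknown variant {self.variant!r}")
        if (self.variant == "epsilon_greedy") != (self.epsilon is not None):
            raise PlannerError("epsilon must be given iff variant='epsilon_greedy'")
        if (self.variant == "softmax") != (self.beta is not None):
            raise PlannerError("beta must be given iff variant='softmax'")
        if self.epsilon is not None and not 0 <= self.epsilon <= 1:
            raise PlannerError(f"epsilon must be in [0,1], got {self.epsilon}")
        if self.beta is not None and self.beta < 0:
            raise PlannerError(f"beta must be >= 0, got {self.beta}")


@dataclass(frozen=True)
class Rollout:
    """One simulated no-backtracking episode."""

    problem_id: str
    config: PlannerConfig
    trajectory: Path
    gems_collected: int
    solved: bool
    termination: str  # "all_gems" | "dead_end"


@dataclass(frozen=True)
class RolloutPMF:
    """Empirical distribution of gems collected over R planner instances."""

    problem_id: str
    config: PlannerConfig
    probabilities: tuple[float, ...]  # support 0..G
    R: int

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities)
        if self.R < 1 or (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
            raise PlannerError("invalid pmf")

    @property
    def support_size(self) -> int:
        return len(self.probabilities)


class PlanCache:
    """Memo for partial-path enumeration, shared across rollouts of a problem.

    Successive instances of the same planner traverse largely the same
    (position, visited-set) states, so caching the enumeration makes large
    instance counts cheap.
    """

    def __init__(self) -> None:
        self._store: dict = {}

    def get(self, key):
        return self._store.get(key)

    def put(self, key, value) -> None:
        self._store[key] = value

    def __len__(self) -> int:
        return len(self._store)


def _uncollected_gems(problem: GridProblem, blocked: set[Node], current: Node) -> list[Node]:
    return [g for g in problem.gems if g != current and g not in blocked]


def enumerate_partial_paths(
    problem: GridProblem,
    current: Node,
    visited: Iterable[Node],
    k: int,
    *,
    shortest_only: bool = False,
    max_length: Optional[int] = None,
    cache: Optional[PlanCache] = None,
) -> tuple[Path, ...]:
    """All simple paths from ``current`` that collect exactly ``k`` gems.

    A returned path avoids ``visited`` (``current`` itself may appear in
    ``visited``; it is treated as the occupied start), contains exactly
    ``k`` uncollected gems and terminates at the ``k``-th. With
    ``shortest_only`` the search runs iterative deepening with an
    admissible lower bound (full-graph BFS distances) and returns only the
    minimum-length candidates; otherwise all candidates up to
    ``max_length`` edges (unbounded if ``None``) are enumerated.
    """
    if k < 1:
        raise PlannerError(f"k must be >= 1, got {k}")
    adj = problem.adjacency()
    if current not in adj:
        raise GridworldError(f"unknown node {current}")
    blocked = set(visited)
    blocked.discard(current)
    gems_left = _uncollected_gems(problem, blocked, current)
    if k > len(gems_left):
        return ()

    key = None
    if cache is not None:
        key = (current, frozenset(blocked), k, shortest_only, max_length)
        hit = cache.get(key)
        if hit is not None:
            return hit

    dist = problem.distances()
    gem_set = set(gems_left)
    results: list[Path] = []
    path: list[Node] = [current]
    on_path: set[Node] = {current} | blocked

    def lower_bound(node: Node, needed: int, collected_on_path: set[Node]) -> Optional[int]:
        # admissible: full-graph distance to the nearest still-needed gem,
        # plus one edge per additional gem
        best = None
        d_node = dist[node]
        for g in gem_set:
            if g in collected_on_path:
                continue
            d = d_node.get(g)
            if d is not None and (best is None or d < best):
                best = d
        if best is None:
            return None
        return best + (needed - 1)

    def dfs(node: Node, got: int, limit: Optional[int], collected: set[Node]) -> None:
        for v in adj[node]:
            if v in on_path:
                continue
            new_len = len(path)  # edges after appending v
            is_gem = v in gem_set
            n_got = got + (1 if is_gem else 0)
            if is_gem and n_got == k:
                if limit is None or new_len <= limit:
                    results.append(Path(tuple(path) + (v,)))
                continue
            if limit is not None:
                need = k - n_got
                lb = lower_bound(v, need, collected | ({v} if is_gem else set()))
                if lb is None or new_len + lb > limit:
                    continue
            path.append(v)
            on_path.add(v)
            if is_gem:
                collected.add(v)
            dfs(v, n_got, limit, collected)
            if is_gem:
                collected.discard(v)
            on_path.discard(v)
            path.pop()

    if shortest_only:
        lb0 = lower_bound(current, k, set())
        out: tuple[Path, ...] = ()
        if lb0 is not None:
            max_possible = problem.width * problem.height - len(blocked) - 1
            for limit in range(lb0, max_possible + 1):
                dfs(current, 0, limit, set())
                if results:
                    best = min(p.length for p in results)
                    out = tuple(p for p in results if p.length == best)
                    break
    else:
        dfs(current, 0, max_length, set())
        out = tuple(results)

    out = tuple(sorted(out, key=lambda p: (p.length, p.nodes)))
    if cache is not None:
        cache.put(key, out)
    return out


def select_plan(
    candidates: Sequence[Path], config: PlannerConfig, rng: np.random.Generator
) -> Path:
    """Pick one candidate path per the variant's selection rule."""
    if not candidates:
        raise PlannerError("select_plan requires a nonempty candidate set")
    ordered = sorted(candidates, key=lambda p: (p.length, p.nodes))
    if config.variant == "softmax":
        lengths = np.array([p.length for p in ordered], dtype=float)
        logits = -config.beta * (lengths - lengths.min())
        w = np.exp(logits)
        return ordered[rng.choice(len(ordered), p=w / w.sum())]
    best = ordered[0].length
    ties = [p for p in ordered if p.length == best]
    if len(ties) == 1:
        return ties[0]
    return ties[int(rng.integers(len(ties)))]


def dead_end_gems(
    problem: GridProblem, remaining_gems: Iterable[Node], visited: Iterable[Node] = ()
) -> set[Node]:
    """Gems that must come last: degree <= 1 in the unvisited subgraph, or
    all of whose unvisited neighbours have degree <= 1 there."""
    adj = problem.adjacency()
    gone = set(visited)
    deg = {
        v: sum(1 for u in adj[v] if u not in gone)
        for v in adj
        if v not in gone
    }
    low = {v for v, d in deg.items() if d <= 1}
    out = set()
    for g in remaining_gems:
        if g in gone:
            continue
        if g in low:
            out.add(g)
            continue
        nbrs = [u for u in adj[g] if u not in gone]
        if nbrs and all(u in low for u in nbrs):
            out.add(g)
    return out


def filter_obvious_ending(
    problem: GridProblem,
    candidates: Sequence[Path],
    remaining_gems: Iterable[Node],
    visited: Iterable[Node] = (),
) -> tuple[Path, ...]:
    """Drop plans in which a dead-end gem is not the final gem of the trial.

    If the plan does not finish the problem (it collects fewer gems than
    remain), any dead-end gem inside it would be followed by more gems, so
    such plans are dropped outright; in a finishing plan the dead-end gem
    must be the terminal node.
    """
    remaining = set(remaining_gems)
    dead = dead_end_gems(problem, remaining, visited)
    if not dead:
        return tuple(candidates)
    kept = []
    for p in candidates:
        on_path = [n for n in p.nodes if n in dead]
        finishes = sum(1 for n in p.nodes if n in remaining) == len(remaining)
        if not on_path:
            kept.append(p)
        elif finishes and len(on_path) == 1 and p.nodes[-1] in dead:
            kept.append(p)
    return tuple(kept)


def rollout(
    problem: GridProblem,
    config: PlannerConfig,
    rng: np.random.Generator,
    cache: Optional[PlanCache] = None,
) -> Rollout:
    """Simulate one no-backtracking episode of the configured planner."""
    home = problem.home
    visited: set[Node] = {home}
    trajectory: list[Node] = [home]
    current = home
    termination = "dead_end"
    eps = config.epsilon if config.variant == "epsilon_greedy" else 0.0

    while True:
        remaining = [g for g in problem.gems if g not in visited]
        if not remaining:
            termination = "all_gems"
            break
        k = min(config.depth, len(remaining))
        if config.variant == "softmax":
            shortest = enumerate_partial_paths(
                problem, current, visited, k, shortest_only=True, cache=cache
            )
            if not shortest:
                break
            cands = enumerate_partial_paths(
                problem, current, visited, k,
                max_length=shortest[0].length + SOFTMAX_LENGTH_WINDOW, cache=cache,
            )
        else:
            cands = enumerate_partial_paths(
                problem, current, visited, k, shortest_only=True, cache=cache
            )
        if config.variant == "obvious_ending" and cands:
            filtered = filter_obvious_ending(problem, cands, remaining, visited)
            # an empty filter result would deadlock the episode artificially;
            # fall back to the unconstrained candidates
            cands = filtered or cands
        if not cands:
            break
        plan = select_plan(cands, config, rng)
        stranded = False
        for step in plan.nodes[1:]:
            if eps > 0 and rng.random() < eps:
                moves = sorted(legal_moves(problem, visited, current))
                if not moves:
                    stranded = True
                    break
                step = moves[int(rng.integers(len(moves)))]
                visited.add(step)
                trajectory.append(step)
                current = step
                break  # replan from the deviated position
            visited.add(step)
            trajectory.append(step)
            current = step
        if stranded:
            break

    traj = Path(tuple(trajectory))
    gems_collected = sum(1 for n in traj.nodes if n in problem.gems)
    solved = gems_collected == problem.num_gems
    return Rollout(
        problem_id=problem.id,
        config=config,
        trajectory=traj,
        gems_collected=gems_collected,
        solved=solved,
        termination="all_gems" if solved else "dead_end",
    )


def rollout_rng(
    master_seed: int, problem_id: str, instance: int, config_tag: str = ""
) -> np.random.Generator:
    """Per-rollout generator derived from (master seed, problem id, instance).

    ``config_tag`` folds the planner's identity into the stream so that
    each member of the planner family gets independent instances --
    without it, two configurations that happen to behave identically
    (e.g. depths beyond the gem count) would produce byte-identical
    outcome samples and artificial likelihood ties downstream.
    """
    tag = zlib.crc32(f"{problem_id}|{config_tag}".encode())
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(tag, instance))
    return np.random.default_rng(ss)


def _config_tag(config: PlannerConfig) -> str:
    return f"{config.depth}|{config.variant}|{config.epsilon}|{config.beta}"


def rollout_pmf(
    problem: GridProblem,
    config: PlannerConfig,
    R: int = DEFAULT_INSTANCES,
    cache: Optional[PlanCache] = None,
) -> RolloutPMF:
    """Empirical pmf of gems collected across ``R`` independent instances."""
    if R < 1:
        raise PlannerError(f"R must be >= 1, got {R}")
    counts = np.zeros(problem.num_gems + 1, dtype=np.int64)
    tag = _config_tag(config)
    for i in range(R):
        rng = rollout_rng(config.seed, problem.id, i, tag)
        counts[rollout(problem, config, rng, cache).gems_collected] += 1
    return RolloutPMF(
        problem_id=problem.id,
        config=config,
        probabilities=tuple(counts / R),
        R=R,
    )


def family_pmfs(
    problems: Sequence[GridProblem],
    R: int = DEFAULT_INSTANCES,
    seed: int = 0,
    depths: Sequence[int] = tuple(range(1, 9)),
    variant: str = "base",
    caches: Optional[dict[str, PlanCache]] = None,
    **variant_params,
) -> dict[str, dict[int, RolloutPMF]]:
    """Outcome pmfs for every (problem, depth) of one planner variant."""
    caches = caches if caches is not None else {}
    out: dict[str, dict[int, RolloutPMF]] = {}
    for problem in problems:
        cache = caches.setdefault(problem.id, PlanCache())
        out[problem.id] = {
            d: rollout_pmf(
                problem,
                PlannerConfig(depth=d, variant=variant, seed=seed, **variant_params),
                R,
                cache,
            )
            for d in depths
        }
    return out


class _BranchCapExceeded(Exception):
    pass


def solvable_at_depth(
    problem: GridProblem,
    depth: int,
    *,
    branch_cap: int = 100_000,
    cache: Optional[PlanCache] = None,
) -> bool:
    """Can *some* realization of the depth-``depth`` base planner solve this?

    Exact enumeration of the planner's stochastic branch tree: the only
    randomness is the uniform tie-break among equal-shortest plans, so the
    tree branches exactly over those ties. Memoized on (position, visited).
    Raises :class:`_BranchCapExceeded` internally past ``branch_cap``
    states; see :func:`classify_min_depth` for the Monte Carlo fallback.
    """
    gems = problem.gems
    memo: dict = {}
    expanded = 0

    def solve(current: Node, visited: frozenset[Node]) -> bool:
        nonlocal expanded
        remaining = len(gems - visited)
        if remaining == 0:
            return True
        key = (current, visited)
        if key in memo:
            return memo[key]
        expanded += 1
        if expanded > branch_cap:
            raise _BranchCapExceeded
        k = min(depth, remaining)
        cands = enumerate_partial_paths(
            problem, current, visited, k, shortest_only=True, cache=cache
        )
        ok = False
        for p in cands:
            if solve(p.nodes[-1], visited | frozenset(p.nodes)):
                ok = True
                break
        memo[key] = ok
        return ok

    return solve(problem.home, frozenset({problem.home}))


def classify_min_depth(
    problem: GridProblem,
    max_depth: int = 8,
    *,
    branch_cap: int = 100_000,
    r_classify: int = 1_000,
    cache: Optional[PlanCache] = None,
) -> "int | str":
    """Smallest depth at which the base planner solves with non-zero probability.

    Primary method is the exact branch-tree enumeration; when that exceeds
    ``branch_cap`` states the decision for that depth falls back to Monte
    Carlo (``r_classify`` seeded rollouts, success meaning at least one
    solves). Returns :data:`UNCLASSIFIABLE` if no depth up to ``max_depth``
    works.
    """
    cache = cache if cache is not None else PlanCache()
    for depth in range(1, max_depth + 1):
        try:
            ok = solvable_at_depth(problem, depth, branch_cap=branch_cap, cache=cache)
        except _BranchCapExceeded:
            config = PlannerConfig(depth=depth, seed=7)
            ok = any(
                rollout(problem, config, rollout_rng(7, problem.id, i), cache).solved
                for i in range(r_classify)
            )
        if ok:
            return depth
    return UNCLASSIFIABLE
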