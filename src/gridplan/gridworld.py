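"""Grid-world problem domain: lattice graphs with a home node and gems.

A problem is a ``width x height`` grid graph (4-neighbour connectivity, some
edges removed) with a start ("home") node and a set of target ("gem") nodes.
A trial solves the problem by tracing one simple path -- a path that never
revisits a node -- from home through every gem.

Nodes are ``(row, col)`` tuples, 0-based, row-major, origin at the top-left;
they serialize as ``"r,c"`` strings in the JSON problem format.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np

Node = tuple[int, int]
Edge = tuple[Node, Node]

DEFAULT_EXPANSION_CAP = 2_000_000
UNDECIDED = "undecided"


class GridworldError(Exception):
    """Base error for the problem domain."""


class FormatError(GridworldError):
    """Malformed problem file."""


class GenerationError(GridworldError):
    """Problem or benchmark generation exhausted its attempt budget."""


def parse_node(text: str) -> Node:
    try:
        r, c = text.split(",")
        return (int(r), int(c))
    except (ValueError, AttributeError) as exc:
        raise FormatError(f"cannot parse node {text!r} (expected 'r,c')") from exc


def format_node(node: Node) -> str:
    return f"{node[0]},{node[1]}"


def canonical_edge(a: Node, b: Node) -> Edge:
    return (a, b) if a <= b else (b, a)


def full_lattice_edges(width: int, height: int) -> set[Edge]:
    """All 4-neighbour edges of the complete ``width x height`` lattice.

    ``height`` counts rows, ``width`` counts columns.
    """
    edges: set[Edge] = set()
    for r in range(height):
        for c in range(width):
            if c + 1 < width:
                edges.add(canonical_edge((r, c), (r, c + 1)))
            if r + 1 < height:
                edges.add(canonical_edge((r, c), (r + 1, c)))
    return edges


@dataclass
class GridProblem:
    """One gem-collection puzzle on a grid graph.

    ``min_depth`` is the smallest planning depth at which the depth-limited
    planner solves the problem with non-zero probability; it is ``None``
    until filled in by classification.
    """

    id: str
    width: int
    height: int
    edges: frozenset[Edge]
    home: Node
    gems: frozenset[Node]
    level: int = 1
    reward_color: str = "red"
    min_depth: Optional[int] = None
    _adj: Optional[dict[Node, tuple[Node, ...]]] = field(
        default=None, repr=False, compare=False
    )
    _dist: Optional[dict[Node, dict[Node, int]]] = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        self.edges = frozenset(canonical_edge(a, b) for a, b in self.edges)
        self.gems = frozenset(self.gems)
        self.validate()

    def validate(self) -> None:
        nodes = self.nodes()
        if self.home not in nodes:
            raise GridworldError(f"home {self.home} outside {self.width}x{self.height} lattice")
        if self.home in self.gems:
            raise GridworldError("home coincides with a gem")
        for g in self.gems:
            if g not in nodes:
                raise GridworldError(f"gem {g} outside lattice")
        lattice = full_lattice_edges(self.width, self.height)
        bad = self.edges - lattice
        if bad:
            raise GridworldError(f"non-lattice edges: {sorted(bad)[:3]}")
        if self.reward_color not in ("red", "blue"):
            raise GridworldError(f"reward_color must be red or blue, got {self.reward_color!r}")
        if self.min_depth is not None and not (1 <= self.min_depth <= 8):
            raise GridworldError(f"min_depth out of range: {self.min_depth}")

    def nodes(self) -> set[Node]:
        return {(r, c) for r in range(self.height) for c in range(self.width)}

    @property
    def num_gems(self) -> int:
        return len(self.gems)

    @property
    def edge_density(self) -> float:
        """Fraction of possible 4-neighbour lattice edges that are present."""
        total = len(full_lattice_edges(self.width, self.height))
        return len(self.edges) / total

    def adjacency(self) -> dict[Node, tuple[Node, ...]]:
        """Sorted adjacency lists (cached; deterministic iteration order)."""
        if self._adj is None:
            adj: dict[Node, list[Node]] = {n: [] for n in sorted(self.nodes())}
            for a, b in sorted(self.edges):
                adj[a].append(b)
                adj[b].append(a)
            self._adj = {n: tuple(sorted(vs)) for n, vs in adj.items()}
        return self._adj

    def distances(self) -> dict[Node, dict[Node, int]]:
        """All-pairs BFS shortest-path lengths on the full problem graph."""
        if self._dist is None:
            adj = self.adjacency()
            dist: dict[Node, dict[Node, int]] = {}
            for src in adj:
                d = {src: 0}
                frontier = [src]
                while frontier:
                    nxt = []
                    for u in frontier:
                        for v in adj[u]:
                            if v not in d:
                                d[v] = d[u] + 1
                                nxt.append(v)
                    frontier = nxt
                dist[src] = d
            self._dist = dist
        return self._dist

    def with_min_depth(self, depth: Optional[int]) -> "GridProblem":
        return replace(self, min_depth=depth, _adj=self._adj, _dist=self._dist)


@dataclass(frozen=True)
class Path:
    """A simple path: consecutive nodes adjacent, no node repeated."""

    nodes: tuple[Node, ...]

    def __post_init__(self) -> None:
        if len(set(self.nodes)) != len(self.nodes):
            raise GridworldError("path repeats a node")

    def __len__(self) -> int:
        return len(self.nodes)

    @property
    def length(self) -> int:
        """Number of edges."""
        return len(self.nodes) - 1

    def validate_on(self, problem: GridProblem) -> None:
        adj = problem.adjacency()
        for a, b in zip(self.nodes, self.nodes[1:]):
            if b not in adj[a]:
                raise GridworldError(f"{a}->{b} is not an edge of {problem.id}")


def legal_moves(problem: GridProblem, visited: set[Node], current: Node) -> set[Node]:
    """Unvisited graph neighbours of ``current``.

    ``current`` is conventionally already in ``visited`` but need not be.
    """
    adj = problem.adjacency()
    if current not in adj:
        raise GridworldError(f"unknown node {current}")
    return {v for v in adj[current] if v not in visited}


@dataclass(frozen=True)
class SolvabilityResult:
    status: "bool | str"  # True / False / UNDECIDED
    witness: Optional[Path] = None
    expansions: int = 0

    def __bool__(self) -> bool:
        return self.status is True


def _reachable_covers(
    adj: dict[Node, tuple[Node, ...]],
    start: Node,
    blocked: set[Node],
    targets: set[Node],
) -> bool:
    """BFS check: are all ``targets`` reachable from ``start`` avoiding ``blocked``?"""
    if not targets:
        return True
    seen = {start}
    frontier = [start]
    todo = set(targets)
    todo.discard(start)
    while frontier and todo:
        nxt = []
        for u in frontier:
            for v in adj[u]:
                if v not in seen and v not in blocked:
                    seen.add(v)
                    todo.discard(v)
                    nxt.append(v)
        frontier = nxt
    return not todo


def find_covering_path(
    problem: GridProblem,
    required: Iterable[Node] = (),
    banned: Iterable[Node] = (),
    expansion_cap: int = DEFAULT_EXPANSION_CAP,
) -> SolvabilityResult:
    """Search for a simple path from home through all gems and ``required``.

    Depth-first search over simple paths with a connectivity pruning rule:
    a branch is abandoned as soon as some still-needed node becomes
    unreachable in the unvisited subgraph. ``banned`` nodes may not be
    entered at all. Exceeding ``expansion_cap`` node expansions yields
    status :data:`UNDECIDED` rather than a verdict.
    """
    adj = problem.adjacency()
    banned_set = set(banned)
    if problem.home in banned_set:
        return SolvabilityResult(False)
    targets = set(problem.gems) | set(required)
    if targets & banned_set:
        return SolvabilityResult(False)
    for t in targets | {problem.home}:
        if t not in adj:
            raise GridworldError(f"unknown node {t}")

    expansions = 0
    path = [problem.home]
    visited = {problem.home} | banned_set

    def dfs(current: Node, remaining: set[Node]) -> Optional[bool]:
        nonlocal expansions
        if not remaining:
            return True
        expansions += 1
        if expansions > expansion_cap:
            return None  # undecided
        blocked = visited - {current}
        if not _reachable_covers(adj, current, blocked, remaining):
            return False
        for v in adj[current]:
            if v in visited:
                continue
            visited.add(v)
            path.append(v)
            sub = dfs(v, remaining - {v})
            if sub:
                return True
            visited.discard(v)
            path.pop()
            if sub is None:
                return None
        return False

    out = dfs(problem.home, targets - {problem.home})
    if out is None:
        return SolvabilityResult(UNDECIDED, expansions=expansions)
    if out:
        return SolvabilityResult(True, witness=Path(tuple(path)), expansions=expansions)
    return SolvabilityResult(False, expansions=expansions)


def is_solvable(
    problem: GridProblem, expansion_cap: int = DEFAULT_EXPANSION_CAP
) -> SolvabilityResult:
    """Does a simple path from home collect every gem?

    Returns a result whose ``status`` is ``True``, ``False`` or
    :data:`UNDECIDED` (expansion cap hit; callers typically resample).
    """
    return find_covering_path(problem, expansion_cap=expansion_cap)


# ---------------------------------------------------------------------------
# Generation


def generate_problem(
    width: int,
    height: int,
    num_gems: int,
    target_density: float,
    rng: np.random.Generator,
    *,
    id: Optional[str] = None,
    level: int = 1,
    max_attempts: int = 10_000,
    placement_attempts: int = 400,
    expansion_cap: int = DEFAULT_EXPANSION_CAP,
) -> GridProblem:
    """Sample a solvable problem.

    Each lattice edge is kept independently with probability
    ``target_density``, then home and gems are placed uniformly without
    collision, resampling the *placement* until the problem is solvable.
    The grid graph itself is redrawn only if no solvable placement exists
    (rare at the default density), so the delivered edge-density
    distribution stays centred on the target instead of drifting upward
    the way reject-the-whole-board sampling would.
    """
    if num_gems > width * height - 1:
        raise GenerationError(f"{num_gems} gems do not fit a {width}x{height} grid")
    if not (0 < target_density <= 1):
        raise GenerationError(f"target_density must be in (0, 1], got {target_density}")
    lattice = sorted(full_lattice_edges(width, height))
    all_nodes = sorted((r, c) for r in range(height) for c in range(width))
    for _ in range(max_attempts):
        keep = rng.random(len(lattice)) < target_density
        edges = frozenset(e for e, k in zip(lattice, keep) if k)
        color = "red" if rng.random() < 0.5 else "blue"
        pid = id if id is not None else f"p{width}x{height}-{rng.integers(1 << 62):016x}"
        for _ in range(placement_attempts):
            picks = rng.choice(len(all_nodes), size=num_gems + 1, replace=False)
            problem = GridProblem(
                id=pid, width=width, height=height, edges=edges,
                home=all_nodes[picks[0]],
                gems=frozenset(all_nodes[i] for i in picks[1:]),
                level=level, reward_color=color,
            )
            if is_solvable(problem, expansion_cap=expansion_cap).status is True:
                return problem
    raise GenerationError(
        f"no solvable {width}x{height} problem with {num_gems} gems "
        f"at density {target_density} in {max_attempts} attempts"
    )


@dataclass(frozen=True)
class BenchmarkDesign:
    """The level x sublevel benchmark layout.

    Three levels of growing grid size and gem count, each split into three
    sublevels binned by required planning depth: {1}, {2..4} and {5..8}.
    """

    levels: tuple[tuple[int, int, tuple[int, int]], ...] = (
        (5, 5, (4, 5)),
        (6, 6, (6, 7)),
        (8, 6, (8, 8)),  # (width, height, (min gems, max gems))
    )
    depth_bins: tuple[tuple[int, int], ...] = ((1, 1), (2, 4), (5, 8))
    problems_per_sublevel: int = 10
    target_density: float = 0.75

    def __post_init__(self) -> None:
        flat = [d for lo, hi in self.depth_bins for d in range(lo, hi + 1)]
        if len(flat) != len(set(flat)) or flat != sorted(flat):
            raise GridworldError("depth bins must be disjoint and ordered")

    def depth_bin_id(self, min_depth: int) -> int:
        """Map a minimum depth to its 1-based sublevel bin (the depthID)."""
        for i, (lo, hi) in enumerate(self.depth_bins, start=1):
            if lo <= min_depth <= hi:
                return i
        raise GridworldError(f"min_depth {min_depth} outside every bin")


def generate_benchmark(
    design: BenchmarkDesign,
    rng: np.random.Generator,
    *,
    max_attempts_per_bin: int = 20_000,
) -> list[GridProblem]:
    """Generate the full benchmark: quota-filled problems per level x sublevel.

    Loops generate -> classify -> keep/discard until each sublevel's quota of
    problems whose classified ``min_depth`` falls in its depth bin is met.
    """
    from .planners import classify_min_depth  # deferred: planners builds on gridworld

    problems: list[GridProblem] = []
    for level_idx, (width, height, (gmin, gmax)) in enumerate(design.levels, start=1):
        for bin_idx, (lo, hi) in enumerate(design.depth_bins, start=1):
            quota = design.problems_per_sublevel
            kept = 0
            attempts = 0
            # a problem of depth d needs at least d gems
            g_lo = max(gmin, lo)
            if g_lo > gmax:
                raise GenerationError(
                    f"level {level_idx} sublevel {bin_idx}: bin {lo}..{hi} "
                    f"needs more gems than the level allows"
                )
            while kept < quota:
                attempts += 1
                if attempts > max_attempts_per_bin:
                    raise GenerationError(
                        f"quota unreachable for level {level_idx} sublevel "
                        f"{bin_idx} (depths {lo}..{hi}) within {max_attempts_per_bin} attempts"
                    )
                num_gems = int(rng.integers(g_lo, gmax + 1))
                prob = generate_problem(
                    width, height, num_gems, design.target_density, rng, level=level_idx
                )
                depth = classify_min_depth(prob)
                if isinstance(depth, int) and lo <= depth <= hi:
                    kept += 1
                    problems.append(
                        replace(
                            prob,
                            id=f"L{level_idx}S{bin_idx}-{kept:02d}",
                            min_depth=depth,
                        )
                    )
    return problems


# ---------------------------------------------------------------------------
# Problem file I/O

_REQUIRED_KEYS = ("id", "level", "width", "height", "home", "gems", "edges")


def _problem_to_dict(p: GridProblem) -> dict:
    return {
        "id": p.id,
        "level": p.level,
        "width": p.width,
        "height": p.height,
        "home": format_node(p.home),
        "gems": [format_node(g) for g in sorted(p.gems)],
        "edges": [[format_node(a), format_node(b)] for a, b in sorted(p.edges)],
        "reward_color": p.reward_color,
        "min_depth": p.min_depth,
        "edge_density": p.edge_density,
    }


def _problem_from_dict(d: dict, index: int) -> GridProblem:
    for key in _REQUIRED_KEYS:
        if key not in d:
            raise FormatError(f"problem #{index}: missing field {key!r}")
    try:
        problem = GridProblem(
            id=str(d["id"]),
            level=int(d["level"]),
            width=int(d["width"]),
            height=int(d["height"]),
            home=parse_node(d["home"]),
            gems=frozenset(parse_node(g) for g in d["gems"]),
            edges=frozenset(
                canonical_edge(parse_node(a), parse_node(b)) for a, b in d["edges"]
            ),
            reward_color=d.get("reward_color", "red"),
            min_depth=d.get("min_depth"),
        )
    except GridworldError as exc:
        raise FormatError(f"problem #{index}: {exc}") from exc
    stored = d.get("edge_density")
    if stored is not None and abs(stored - problem.edge_density) > 1e-12:
        raise FormatError(
            f"problem #{index}: stored edge_density {stored} disagrees with "
            f"recomputed {problem.edge_density}"
        )
    return problem


def write_problems(problems: Sequence[GridProblem], path) -> None:
    payload = {"problems": [_problem_to_dict(p) for p in problems]}
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1, sort_keys=False)
        fh.write("\n")


def read_problems(path) -> list[GridProblem]:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    if not isinstance(payload, dict) or "problems" not in payload:
        raise FormatError("top level must be an object with a 'problems' array")
    return [_problem_from_dict(d, i) for i, d in enumerate(payload["problems"])]
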