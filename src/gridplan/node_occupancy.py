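"""Graph-theoretic node-occupancy models.

Which intermediate nodes do solvers pass through, beyond the ones they have
no choice about? Candidate nodes are those lying on at least one complete
solution but not on *every* solution (the latter -- including home and all
gems -- are forced choices and carry no information). Each of seven metrics
scores the candidates; a SoftMax with temperature ``tau`` turns scores into
an occupancy distribution, and metrics compete on the log-likelihood of
observed node visits with ``tau`` fitted per metric by maximum likelihood.

Metrics: eigenvector / closeness / degree / betweenness centrality (standard
definitions on the full problem graph), ``random`` (uniform over
candidates), ``shortest_path`` (fraction of minimum-length complete
solutions through the node) and ``rgi`` (relevant goal information: the
mutual information, in bits, between which gem is pursued next and the
locally optimal move at the node).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import optimize

from .gridworld import (
    DEFAULT_EXPANSION_CAP,
    GridProblem,
    GridworldError,
    Node,
    find_covering_path,
)
from .planners import enumerate_partial_paths

METRICS = (
    "eigenvector", "rgi", "closeness", "degree",
    "random", "betweenness", "shortest_path",
)


class OccupancyError(GridworldError):
    pass


@dataclass(frozen=True)
class NodeScoreTable:
    problem_id: str
    metric: str
    scores: Mapping[Node, float]  # candidate nodes only

    def __post_init__(self) -> None:
        if not all(math.isfinite(v) for v in self.scores.values()):
            raise OccupancyError(f"non-finite {self.metric} score")


@dataclass(frozen=True)
class OccupancyModel:
    metric: str
    tau: float
    probabilities: Mapping[Node, float]


def to_networkx(problem: GridProblem) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(problem.nodes())
    g.add_edges_from(problem.edges)
    return g


def forced_nodes(
    problem: GridProblem, expansion_cap: int = DEFAULT_EXPANSION_CAP
) -> set[Node]:
    """Nodes contained in every complete solution (always home and gems).

    A node is forced iff banning it destroys solvability.
    """
    base = find_covering_path(problem, expansion_cap=expansion_cap)
    if base.status is not True:
        raise OccupancyError(f"problem {problem.id} is not (decidably) solvable")
    forced = {problem.home} | set(problem.gems)
    for v in sorted(problem.nodes() - forced):
        if find_covering_path(problem, banned={v}, expansion_cap=expansion_cap).status is not True:
            forced.add(v)
    return forced


def solution_nodes(
    problem: GridProblem, expansion_cap: int = DEFAULT_EXPANSION_CAP
) -> set[Node]:
    """Nodes lying on at least one complete solution."""
    base = find_covering_path(problem, expansion_cap=expansion_cap)
    if base.status is not True:
        raise OccupancyError(f"problem {problem.id} is not (decidably) solvable")
    on = {problem.home} | set(problem.gems)
    for v in sorted(problem.nodes() - on):
        if find_covering_path(problem, required={v}, expansion_cap=expansion_cap).status is True:
            on.add(v)
    return on


def candidate_nodes(problem: GridProblem) -> set[Node]:
    """Solution nodes that are not forced: the occupancy analysis domain."""
    return solution_nodes(problem) - forced_nodes(problem)


def _rgi_score(problem: GridProblem, node: Node) -> float:
    """Goal-move mutual information (bits) at ``node`` on the full graph.

    The goal is the next gem to pursue, uniform over gems reachable from
    the node; given a goal, the move is uniform over the neighbours that
    start a shortest path to it. Zero bits means the best move does not
    depend on the goal.
    """
    dist = problem.distances()
    adj = problem.adjacency()
    moves = adj[node]
    gems = [g for g in sorted(problem.gems) if g in dist[node]]
    if not gems or not moves:
        return 0.0
    p_goal = 1.0 / len(gems)
    p_move: Counter = Counter()
    conditionals = []
    for g in gems:
        d = dist[node][g]
        best = [m for m in moves if dist[m].get(g, math.inf) == d - 1]
        cond = {m: 1.0 / len(best) for m in best}
        conditionals.append(cond)
        for m, q in cond.items():
            p_move[m] += p_goal * q
    mi = 0.0
    for cond in conditionals:
        for m, q in cond.items():
            mi += p_goal * q * math.log2(q / p_move[m])
    return max(mi, 0.0)


def _shortest_solution_fraction(problem: GridProblem) -> dict[Node, float]:
    """Fraction of minimum-length complete solutions containing each node.

    A minimum-length solution is a shortest simple path from home through
    all gems; it necessarily terminates on its last gem, so the full-depth
    partial-path enumerator yields exactly the optimal solutions.
    """
    solutions = enumerate_partial_paths(
        problem, problem.home, {problem.home}, problem.num_gems, shortest_only=True
    )
    if not solutions:
        raise OccupancyError(f"problem {problem.id} has no complete solution")
    counts: Counter = Counter()
    for path in solutions:
        counts.update(path.nodes)
    return {v: counts.get(v, 0) / len(solutions) for v in problem.nodes()}


def score_nodes(
    problem: GridProblem,
    metric: str,
    candidates: Optional[Iterable[Node]] = None,
) -> NodeScoreTable:
    """Score the candidate (non-forced solution) nodes with one metric.

    Nodes in components unreachable from the rest score 0 where the metric
    involves distances. ``candidates`` can be passed to avoid recomputing
    the (expensive) forced/solution node sets.
    """
    if metric not in METRICS:
        raise OccupancyError(f"unknown metric {metric!r}")
    cand = sorted(candidates) if candidates is not None else sorted(candidate_nodes(problem))
    g = to_networkx(problem)
    if metric == "eigenvector":
        # stray components make the dominant eigenvector ill-defined; all
        # candidates live in home's component, the rest scores 0
        comp = nx.node_connected_component(g, problem.home)
        full = nx.eigenvector_centrality_numpy(g.subgraph(comp))
        scores = {v: abs(full[v]) if v in comp else 0.0 for v in cand}
    elif metric == "closeness":
        full = nx.closeness_centrality(g, wf_improved=False)
        scores = {v: full[v] for v in cand}
    elif metric == "degree":
        scores = {v: float(g.degree(v)) for v in cand}
    elif metric == "betweenness":
        full = nx.betweenness_centrality(g, normalized=True)
        scores = {v: full[v] for v in cand}
    elif metric == "random":
        scores = {v: 1.0 for v in cand}
    elif metric == "shortest_path":
        frac = _shortest_solution_fraction(problem)
        scores = {v: frac[v] for v in cand}
    else:  # rgi
        scores = {v: _rgi_score(problem, v) for v in cand}
    return NodeScoreTable(problem.id, metric, scores)


def occupancy_model(scores: NodeScoreTable, tau: float) -> OccupancyModel:
    """SoftMax occupancy distribution: p(v) proportional to exp(score/tau)."""
    if tau <= 0:
        raise OccupancyError(f"tau must be > 0, got {tau}")
    nodes = sorted(scores.scores)
    vals = np.array([scores.scores[v] for v in nodes], dtype=float)
    logits = (vals - vals.max()) / tau
    w = np.exp(logits)
    w /= w.sum()
    return OccupancyModel(scores.metric, tau, dict(zip(nodes, w)))


def visits_from_trials(trials: Iterable, problems: Sequence[GridProblem]) -> dict[str, Counter]:
    """Per-problem candidate-node visit counts from trial records.

    A candidate node counts once per trial in which it was ever selected
    (trajectory membership, not dwell time); non-candidate selections are
    ignored.
    """
    cand = {p.id: candidate_nodes(p) for p in problems}
    visits: dict[str, Counter] = {p.id: Counter() for p in problems}
    for trial in trials:
        if trial.problem_id not in cand:
            continue
        selected = {e.node for e in trial.events if e.type == "select"}
        for v in selected & cand[trial.problem_id]:
            visits[trial.problem_id][v] += 1
    return visits


def _pooled_nll(
    tables: Sequence[NodeScoreTable],
    visit_counts: Sequence[Mapping[Node, int]],
    tau: float,
) -> float:
    nll = 0.0
    for table, counts in zip(tables, visit_counts):
        model = occupancy_model(table, tau)
        for v, c in counts.items():
            p = model.probabilities.get(v)
            if p is None:
                raise OccupancyError(f"visit to non-candidate node {v}")
            nll -= c * math.log(p)
    return nll


def fit_tau(
    tables: Sequence[NodeScoreTable],
    visit_counts: Sequence[Mapping[Node, int]],
    bounds: tuple[float, float] = (1e-3, 1e3),
) -> tuple[float, float]:
    """MLE temperature for one metric, pooled over problems.

    Returns (tau_hat, nll_at_tau_hat); optimized on a log-tau scale.
    """
    res = optimize.minimize_scalar(
        lambda log_tau: _pooled_nll(tables, visit_counts, math.exp(log_tau)),
        bounds=(math.log(bounds[0]), math.log(bounds[1])),
        method="bounded",
        options={"xatol": 1e-4},
    )
    return math.exp(res.x), float(res.fun)


def compare_occupancy(
    problems: Sequence[GridProblem],
    visits: Mapping[str, Mapping[Node, int]],
    metrics: Sequence[str] = METRICS,
) -> pd.DataFrame:
    """Rank metrics by pooled negative log-likelihood of observed visits.

    One temperature per metric is fitted by MLE across all problems; the
    output table reports fitted tau, NLL, and the NLL excess over the best
    metric (0 for the winner; a tie on the minimum is flagged).
    """
    cand = {p.id: sorted(candidate_nodes(p)) for p in problems}
    visit_lists = [visits.get(p.id, {}) for p in problems]
    rows = []
    for metric in metrics:
        tables = [score_nodes(p, metric, candidates=cand[p.id]) for p in problems]
        if metric == "random":
            # flat scores: tau is irrelevant, skip the fit
            tau_hat, nll = 1.0, _pooled_nll(tables, visit_lists, 1.0)
        else:
            tau_hat, nll = fit_tau(tables, visit_lists)
        rows.append({"metric": metric, "tau": tau_hat, "nll": nll})
    out = pd.DataFrame(rows)
    best = out["nll"].min()
    out["excess_nll"] = out["nll"] - best
    out["tied_best"] = np.isclose(out["nll"], best) & (out["excess_nll"] > 0)
    return out.sort_values("nll", ignore_index=True)
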