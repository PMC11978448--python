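"""Synthetic participant cohorts.

Generates trial event logs with the statistical structure the inference
stack assumes: agents that plan to a fixed depth or adapt their depth to
each problem's minimum requirement, occasionally deviate to a random legal
move (epsilon-greedy execution noise), and on hitting a dead end backtrack
by unselecting every node back to home before replanning. The first
(pre-backtrack) plan of such an agent is by construction one rollout of the
matching planner, which is what makes the cohort a valid test bed for the
likelihood machinery.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .gridworld import FormatError, GridProblem, Node, format_node, parse_node
from .planners import PlanCache, PlannerConfig, rollout


class CohortError(Exception):
    pass


@dataclass(frozen=True)
class SyntheticAgent:
    """A simulated participant with a known planning policy."""

    agent_id: str
    strategy: str  # "fixed" | "adaptive"
    depth: Optional[int] = None  # required for "fixed"
    epsilon: float = 0.0

    def __post_init__(self) -> None:
        if self.strategy not in ("fixed", "adaptive"):
            raise CohortError(f"unknown strategy {self.strategy!r}")
        if self.strategy == "fixed" and not (self.depth and 1 <= self.depth <= 8):
            raise CohortError("fixed strategy needs depth 1..8")
        if not 0 <= self.epsilon <= 1:
            raise CohortError(f"epsilon must be in [0,1], got {self.epsilon}")

    def depth_for(self, problem: GridProblem) -> int:
        if self.strategy == "fixed":
            return self.depth  # type: ignore[return-value]
        if problem.min_depth is None:
            raise CohortError(
                f"adaptive agent needs a classified problem, {problem.id} is not"
            )
        return problem.min_depth


@dataclass(frozen=True)
class TrialEvent:
    index: int
    type: str  # "select" | "unselect"
    node: Node


@dataclass(frozen=True)
class TrialRecord:
    participant_id: str
    problem_id: str
    events: tuple[TrialEvent, ...]
    solved: bool


def simulate_trial(
    agent: SyntheticAgent,
    problem: GridProblem,
    rng: np.random.Generator,
    retry_budget: int = 10,
    cache: Optional[PlanCache] = None,
) -> TrialRecord:
    """One trial: plan forward; on a dead end, unwind to home and replan.

    Each attempt is a fresh no-backtracking rollout of the agent's
    epsilon-greedy planner (epsilon = 0 reduces exactly to the base
    planner). Failed attempts emit unselect events all the way back to
    home -- except the last one, which leaves the trial stranded and
    unsolved once the retry budget is spent.
    """
    depth = agent.depth_for(problem)
    config = PlannerConfig(depth=depth, variant="epsilon_greedy", epsilon=agent.epsilon)
    events: list[TrialEvent] = []
    idx = 0
    solved = False
    for attempt in range(retry_budget + 1):
        out = rollout(problem, config, rng, cache)
        for node in out.trajectory.nodes[1:]:
            events.append(TrialEvent(idx, "select", node))
            idx += 1
        if out.solved:
            solved = True
            break
        if attempt == retry_budget:
            break
        for node in reversed(out.trajectory.nodes[1:]):
            events.append(TrialEvent(idx, "unselect", node))
            idx += 1
    return TrialRecord(agent.agent_id, problem.id, tuple(events), solved)


def extract_first_plan(trial: TrialRecord, problem: GridProblem) -> int:
    """Gems selected strictly before the first unselect event.

    Trials with no backtrack contribute the gems collected over the whole
    trial.
    """
    selected: set[Node] = set()
    for event in trial.events:
        if event.type == "unselect":
            break
        selected.add(event.node)
    return sum(1 for g in problem.gems if g in selected)


def replay_trial(trial: TrialRecord, problem: GridProblem) -> None:
    """Validate stack discipline and adjacency; raises on any violation."""
    adj = problem.adjacency()
    stack: list[Node] = [problem.home]
    for event in trial.events:
        if event.type == "select":
            if event.node in stack:
                raise CohortError(f"re-selects currently selected node {event.node}")
            if event.node not in adj[stack[-1]]:
                raise CohortError(f"{stack[-1]}->{event.node} is not an edge")
            stack.append(event.node)
        elif event.type == "unselect":
            if len(stack) == 1:
                raise CohortError("unselect with empty selection")
            if event.node != stack[-1]:
                raise CohortError(
                    f"unselect {event.node} but top of stack is {stack[-1]}"
                )
            stack.pop()
        else:
            raise CohortError(f"unknown event type {event.type!r}")


def _trial_rng(master_seed: int, agent_id: str, problem_id: str) -> np.random.Generator:
    key = (zlib.crc32(agent_id.encode()), zlib.crc32(problem_id.encode()))
    return np.random.default_rng(np.random.SeedSequence(entropy=master_seed, spawn_key=key))


def generate_cohort(
    problems: Sequence[GridProblem],
    agents: Sequence[SyntheticAgent],
    master_seed: int = 0,
    retry_budget: int = 10,
    caches: Optional[dict[str, PlanCache]] = None,
) -> tuple[list[TrialRecord], pd.DataFrame]:
    """One trial per (agent, problem), plus the extracted observation table.

    Deterministic under ``master_seed``: each trial draws from a generator
    derived from (master seed, agent id, problem id). The observation
    table has columns participant_id, problem_id, gems (before first
    backtrack) and solved.
    """
    if not problems or not agents:
        raise CohortError("need at least one problem and one agent")
    caches = caches if caches is not None else {}
    trials: list[TrialRecord] = []
    rows = []
    for problem in problems:
        cache = caches.setdefault(problem.id, PlanCache())
        for agent in agents:
            rng = _trial_rng(master_seed, agent.agent_id, problem.id)
            trial = simulate_trial(agent, problem, rng, retry_budget, cache)
            trials.append(trial)
            rows.append({
                "participant_id": agent.agent_id,
                "problem_id": problem.id,
                "gems": extract_first_plan(trial, problem),
                "solved": trial.solved,
            })
    return trials, pd.DataFrame(rows)


def write_trials(trials: Iterable[TrialRecord], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for t in trials:
            record = {
                "participant_id": t.participant_id,
                "problem_id": t.problem_id,
                "events": [
                    {"i": e.index, "type": e.type, "node": format_node(e.node)}
                    for e in t.events
                ],
                "solved": t.solved,
            }
            fh.write(json.dumps(record, sort_keys=False))
            fh.write("\n")


def read_trials(path) -> list[TrialRecord]:
    trials = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                d = json.loads(line)
                trials.append(TrialRecord(
                    participant_id=str(d["participant_id"]),
                    problem_id=str(d["problem_id"]),
                    events=tuple(
                        TrialEvent(int(e["i"]), e["type"], parse_node(e["node"]))
                        for e in d["events"]
                    ),
                    solved=bool(d["solved"]),
                ))
            except (KeyError, ValueError, TypeError) as exc:
                raise FormatError(f"trials line {lineno}: {exc}") from exc
    return trials
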