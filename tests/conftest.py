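import numpy as np
import pytest

from gridplan.gridworld import (
    GridProblem,
    canonical_edge,
    full_lattice_edges,
    generate_problem,
)


def make_toy() -> GridProblem:
    """3x3 lattice missing the (2,0)-(2,1) edge; gems at (2,0) and (2,2).

    The gem at (2,0) hangs off a dead end, so the greedy depth-1 planner
    always strands itself there after one gem; depth 2 finds the unique
    Hamiltonian solution. Minimum depth 2.
    """
    edges = full_lattice_edges(3, 3) - {canonical_edge((2, 0), (2, 1))}
    return GridProblem(
        id="P_toy", width=3, height=3, edges=frozenset(edges),
        home=(0, 0), gems=frozenset({(2, 0), (2, 2)}),
    )


def full_grid_problem(width, height, home, gems, id="full") -> GridProblem:
    return GridProblem(
        id=id, width=width, height=height,
        edges=frozenset(full_lattice_edges(width, height)),
        home=home, gems=frozenset(gems),
    )


@pytest.fixture
def p_toy() -> GridProblem:
    return make_toy()


@pytest.fixture(scope="session")
def small_problems() -> list[GridProblem]:
    """Seeded solvable 4x4 problems used across property tests."""
    rng = np.random.default_rng(123)
    return [
        generate_problem(4, 4, 3, 0.8, rng, id=f"s{i}") for i in range(8)
    ]
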