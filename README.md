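# gridplan

Tools for studying **adaptive planning depth** in gem-collection grid
puzzles: benchmark generation, a family of depth-limited planners, and the
likelihood machinery that decides whether an agent's first plans track each
problem's minimum required planning depth.

## The problem

A puzzle is a grid graph (some 4-neighbour edges removed) with a start node
("home") and a set of target nodes ("gems"). A solution is a *simple path*
— never revisiting a node — from home through every gem. Some puzzles yield
to a greedy strategy (always head for the nearest gem); others dead-end the
greedy solver and require planning several gems ahead.

The **depth-n planner** makes this precise: it repeatedly enumerates all
simple partial paths from its current position that collect exactly
`k = min(n, remaining gems)` uncollected gems, commits to the shortest
(uniformly among ties), marks crossed nodes visited and replans — without
ever backtracking. A puzzle's **minimum required depth** is the smallest
`n` at which some realization of this planner solves it, and puzzles are
grouped 1–8 by that depth.

Given observed first plans — the number of gems an agent collects before
its first backtrack — the package asks which depth explains them. For each
puzzle and depth, 500 planner instances give an empirical outcome
distribution; additive smoothing (α = 0.5) turns it into a likelihood;
puzzles then score each depth by rank (0 = best). The headline comparison
is between every fixed-depth model and an **adaptive** model whose depth
equals each puzzle's minimum required depth, tested per depth with a χ²
independence test on rank-0 frequencies and stress-tested by Gaussian
jitter of the log-likelihoods. Noisy planner variants (ε-greedy and
SoftMax with temperature β) are fitted by grid-search maximum likelihood
and compared by AIC/BIC, and seven graph-centrality metrics compete to
explain *which* intermediate nodes solvers occupy.

Because the original participant data is not required, a synthetic cohort
module simulates agents of known strategy (fixed or adaptive depth,
ε-noise, dead-end backtracking) so that every inference stage is testable
as a parameter-recovery exercise.

## Worked example

```python
import numpy as np
import gridplan as gp
from gridplan import depth_inference as di
from gridplan.gridworld import BenchmarkDesign

# an 18-puzzle benchmark (2 per level x depth-bin cell), classified
design = BenchmarkDesign(problems_per_sublevel=2)
problems = gp.generate_benchmark(design, np.random.default_rng(0))

# 65 adaptive agents with 10% execution noise, one trial per puzzle
agents = [gp.SyntheticAgent(f"a{i:02d}", "adaptive", epsilon=0.1)
          for i in range(65)]
caches = {}
trials, obs = gp.generate_cohort(problems, agents, master_seed=1, caches=caches)

# 500 planner instances per (puzzle, depth) -> likelihoods -> ranks
pmfs = gp.family_pmfs(problems, R=500, seed=2, caches=caches)
table = di.likelihood_table(obs, pmfs)
min_depths = {p.id: p.min_depth for p in problems}
records, summary = di.rank_analysis(table, min_depths)
print(summary.round(2))
res = di.adaptive_vs_fixed_test(records, 1)
print(f"adaptive vs fixed depth 1: chi2(1) = {res.statistic:.1f}, "
      f"p = {res.p_value:.2g}")
```

prints

```
          mean_rank  median_rank
model
d1             2.61          2.5
d2             3.61          4.0
d3             3.50          3.0
d4             3.56          3.0
d5             3.28          3.5
d6             4.33          4.5
d7             3.56          4.0
d8             3.56          3.0
adaptive       0.11          0.0
adaptive vs fixed depth 1: chi2(1) = 13.8, p = 0.0002
```

The adaptive model's mean likelihood-rank (0.11) is far below every
fixed-depth model (2.6–4.3): on almost every puzzle, the planner whose
depth matches that puzzle's minimum requirement explains the cohort's
first plans best — which is exactly how the cohort was generated. The χ²
test confirms the adaptive model achieves rank 0 significantly more often
than the fixed depth-1 model.

The same pipeline is scriptable from a shell:

```
gridplan generate --seed 4 --out problems.json
gridplan simulate-cohort --problems problems.json --seed 6 --out trials.jsonl
gridplan infer-depth --problems problems.json --trials trials.jsonl \
    --seed 9 --out results/
gridplan occupancy --problems problems.json --trials trials.jsonl \
    --metrics all --out occupancy.tsv
```

## Layout

- `gridplan.gridworld` — problem domain, solvability search, benchmark
  generation, JSON problem files
- `gridplan.planners` — the depth-n planner family, rollouts, outcome
  pmfs, minimum-depth classification
- `gridplan.depth_inference` — likelihoods, winners, ranks, χ² tests,
  jitter robustness, KL profiles, ε/β fitting, descriptive cell summaries
- `gridplan.node_occupancy` — forced/candidate nodes, seven node metrics,
  SoftMax occupancy models, model comparison
- `gridplan.synthetic_cohort` — synthetic agents, trial event logs,
  first-plan extraction, JSONL trial files
- `gridplan.cli` — the `gridplan` command

See `docs/methods.md` for modelling assumptions, numerical choices and
known limitations.
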