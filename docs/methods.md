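# Methods

## The task and the model family

A problem is a `width x height` grid graph with some 4-neighbour edges
removed, a start node ("home") and a set of target nodes ("gems"). A
solution is a *simple path* — one that never revisits a node — starting at
home and passing through every gem. The scientific question the package
serves is whether solvers' *first plans* commit to the minimum planning
depth a problem requires, rather than to one fixed depth everywhere.

The depth-`n` planner formalizes a bounded plan: from its current position
it enumerates every simple partial path that collects exactly
`k = min(n, remaining gems)` uncollected gems and terminates on the k-th,
commits to the shortest such path (uniformly at random among ties), marks
every crossed node visited, and replans from the end of the committed
segment. It cannot backtrack: if no candidate exists or it runs out of
legal moves mid-plan, the episode ends where it stands. The *minimum
required depth* of a problem is the smallest `n` for which some
realization of this planner solves it; problems are binned by that depth.

Three variants perturb the skeleton:

- **obvious ending** — discards candidate plans in which a *dead-end gem*
  (degree ≤ 1 in the currently unvisited subgraph, or all of whose
  unvisited neighbours have degree ≤ 1) is not the final gem of the trial.
  If the rule would discard every candidate the planner falls back to the
  unconstrained set rather than declaring an artificial dead end.
- **epsilon-greedy** — while executing a committed segment, each
  single-node step is replaced with probability ε by a uniform choice
  among legal moves, after which the agent replans from wherever it landed.
  ε = 0 reproduces the base planner exactly, draw for draw.
- **SoftMax** — replaces the argmin selection with sampling candidate
  paths with probability ∝ exp(−β·length). β ≥ 50 is numerically
  indistinguishable from argmin on integer lengths.

## Inference

For each (participant, problem) the fitted statistic is the number of gems
collected before the first backtrack. Each candidate depth's planner is
simulated R = 500 times per problem (independent seeded instances per
planner configuration), giving an empirical pmf over 0..G gems. Additive
smoothing with α = 0.5 pseudocounts per support cell,
`p̃(x) = (count(x) + α) / (R + α(G+1))`, keeps every observation's
likelihood finite. Per problem, depths are ranked by total log-likelihood
(rank 0 = best; exact ties break toward the lower depth); the *adaptive*
model's rank is the rank of the problem's own minimum-depth planner. The
adaptive-vs-fixed comparison is a χ² independence test on the 2×2 table
(model × achieved-rank-0-or-not), df = 1; a zero-margin table is reported
as no evidence (χ² = 0, p = 1) rather than an error. The jitter
robustness check adds N(0, σ²) noise (default σ = 10⁻⁶ × median |log L|,
just enough to break ties) to every log-likelihood and reports the
fraction of iterations in which the adaptive conclusion — strictly lowest
mean rank and all eight tests rejecting at 0.05 — fails. A KL profile,
KL(observed ‖ planner) per depth on the same smoothed support, provides
the equivalent distribution-level depth selector.

Noise parameters are fitted by grid-search maximum likelihood, re-simulating
the pmf at every grid point under a common master seed (common random
numbers reduce argmax jitter): ε on 0..1 in steps of 0.02, β on 21
log-spaced points in [0.05, 50]. AIC = 2k − 2LL and BIC = k·ln N − 2LL
with k = 1 (k = 0 for the noiseless base planner). Note that at ε = 0 the
ε-greedy and SoftMax fits both collapse to the base planner, so their
AIC/BIC comparison is informative only on data generated with noise.

## Benchmark generation

The standard design is 3 levels × 3 depth sublevels × 10 problems:
5×5 grids with 4–5 gems, 6×6 with 6–7, 8×6 with 8, with sublevels binned
by required depth {1}, {2..4}, {5..8} (the three "depthID" bins). Each
lattice edge is kept independently with probability 0.75 (the target edge
density). Home and gems are then placed uniformly without collision, and
the *placement* is resampled (up to 400 attempts) until the problem is
solvable; the grid graph itself is redrawn only when no solvable placement
exists. This ordering matters: rejecting whole boards until solvable
selects for denser boards and inflates the delivered mean density by
~0.03 at 5×5 with 4 gems, whereas placement-first rejection keeps the
delivered mean within sampling error of the 0.75 target at all three grid
sizes. Sublevel quotas are filled by a generate → classify → keep/discard
loop; bins requiring depth d draw at least d gems. Gem colour (red/blue,
the reward-doubling manipulation) is carried as metadata only and affects
no computation.

## Numerical choices

- **Partial-path enumeration.** Candidates are found by depth-first
  search; the shortest-only mode runs iterative deepening with an
  admissible lower bound (full-graph BFS distance to the nearest needed
  gem plus one edge per further gem). Enumerations are memoized per
  problem on (position, visited set, k), which makes 500 instances of a
  planner barely more expensive than one.
- **SoftMax candidate truncation.** Enumerating *all* simple k-gem paths
  is exponential on 6×8 boards, so the SoftMax planner samples among
  candidates within 6 edges of the shortest; the neglected tail carries
  weight ≤ exp(−6β) relative to the shortest path.
- **Minimum-depth classification** enumerates the planner's stochastic
  branch tree exactly — branching only at shortest-path ties — with
  memoization on (position, visited); past 10⁵ states it falls back to
  Monte Carlo (1,000 rollouts; "non-null probability" ⇔ ≥ 1 success).
  The exact method is cross-checked against a naive brute-force
  enumeration on all test fixtures up to 4×4.
- **Solvability** is exhaustive DFS over simple paths with a
  connectivity-pruning rule and a 2×10⁶-expansion cap; hitting the cap
  yields an explicit "undecided" status (treated as a rejection during
  generation), never a silent verdict.
- **Seeding.** Every stochastic component derives its generator from a
  master seed plus stable identifiers (problem id, instance index, the
  planner configuration, agent id), so runs are bit-reproducible and each
  planner's 500 instances are independent of every other planner's. The
  configuration tag in the derivation is deliberate: planner depths beyond
  a problem's gem count clamp to the same effective depth, and without
  per-configuration streams such twins would yield byte-identical samples
  and artificial likelihood ties.

## Node occupancy

Candidate nodes are those on at least one complete solution but not on
all of them (nodes on every solution — always home and the gems — are
forced choices). Membership is decided by two covering-path searches per
node: banning the node (forced iff unsolvable without it) and requiring
it (on a solution iff solvable through it). Seven metrics score
candidates on the full problem graph: eigenvector, closeness
(reciprocal-of-distance-sum form), degree and betweenness centrality
(standard definitions; eigenvector is computed on home's connected
component, stray components score 0), a uniform "random" baseline, the
fraction of minimum-length complete solutions through the node, and
relevant goal information (RGI) — the mutual information in bits between
which gem is pursued next (uniform over reachable gems) and the locally
optimal move (uniform over neighbours that begin a shortest path to that
gem). RGI is a verbal construct in the source literature; this
formalization is the package's own interpretation. Scores become
occupancy distributions through a SoftMax p(v) ∝ exp(score/τ), with one
temperature per metric fitted by bounded scalar MLE on log τ ∈
[ln 10⁻³, ln 10³]; metrics are compared on pooled negative log-likelihood
of observed visits (a candidate node counts once per trial it appears in).
Fitting τ per metric makes the seven-way comparison fair — a metric is
never penalized for its scale.

## The synthetic cohort

Synthetic agents replace the human participants: each has a strategy
(fixed depth d, or adaptive = the problem's minimum depth), an execution
noise ε, and plans with the ε-greedy planner. A trial runs the planner
forward; on a dead end the agent unselects every node back to home and
replans (retry budget 10), so event logs show the select/unselect stack
discipline of real play. The default cohort is 65 agents with ε = 0.1 on
the 90-problem benchmark — matching the analyzed sample size of the
study design — and the first attempt of every trial *is* one planner
rollout, so the pre-backtrack statistic is exactly the modelled quantity
(asserted by a two-sample χ² comparison at R = 500).

What the generator does not emulate: timing (the 60-second deadline and
completion times), partial backtracking (real players may unwind only a
few nodes; the trial format supports it, the simulator always unwinds to
home), reward-colour effects, fatigue or learning across trials, and any
within-trial change of planning depth. Recovery results on this cohort
therefore show that the inference machinery identifies planning depth and
adaptivity when the generating process matches the model family — they
cannot show that human data satisfies those assumptions.

## Problem sizes used in the shipped checks

The shipped end-to-end checks run the full 90-problem benchmark with 65
agents and R = 500 instances (the study-scale configuration), 1,000
problems for the density calibration, 10⁴ jitter iterations (the original
robustness analysis used 10⁵; the iteration count is a parameter), and
200-trial cohorts per ε for noise recovery. Oracle cross-checks run on
exhaustive sweeps of boards up to 4×4 and graphs up to 12 nodes, where
brute-force enumeration is exact.

## Known limitations

- Whether the original partial-path enumeration allowed paths to cross
  extra gems beyond the k-th is not documented; here a partial plan
  contains exactly k gems and ends on the k-th.
- The SoftMax planner's candidate truncation (above) makes it exact only
  up to a controlled tail.
- Minimum-depth classification is exact up to the branch cap; on boards
  where the cap trips, "non-null probability" is decided by sampling.
- The delivered edge density is conditioned on a solvable placement
  existing, which in principle still excludes a small set of very sparse
  boards; empirically the residual bias is within 2 SE of the target at
  1,000 problems.
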