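"""Planning-depth inference from first-plan observations.

The fitted statistic is, per (participant, problem), the number of gems
collected before the first backtrack. Each candidate depth's planner yields
an empirical pmf of that statistic over R simulated instances; additive
smoothing turns it into a likelihood, and problems are then scored by

* winner frequencies — which depth has the highest likelihood, tallied and
  row-normalized within each minimum-depth problem group;
* rank distributions — per-problem descending-likelihood ranks (0 = best)
  for each fixed depth and for the "adaptive" model whose depth equals each
  problem's minimum required depth;
* a chi-squared independence test of adaptive vs each fixed depth on the
  (model x rank-0-or-not) table, plus a Gaussian-jitter robustness check of
  the whole conclusion against likelihood ties;
* a KL-divergence profile as an alternative depth selector;
* maximum-likelihood fits of the noise parameter (epsilon or beta) with
  AIC/BIC, and the correlation of fitted epsilon with problem depth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .gridworld import BenchmarkDesign, GridProblem
from .planners import PlanCache, PlannerConfig, RolloutPMF, rollout_pmf

DEPTHS = tuple(range(1, 9))
DEFAULT_ALPHA = 0.5
DEFAULT_EPS_GRID = tuple(np.round(np.arange(0.0, 1.0001, 0.02), 2))
DEFAULT_BETA_GRID = tuple(np.logspace(np.log10(0.05), np.log10(50.0), 21))


class InferenceError(Exception):
    pass


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: int
    p_value: float
    rejection_fraction: Optional[float] = None
    degenerate: bool = False


@dataclass(frozen=True)
class NoiseFit:
    """MLE of a planner noise parameter on one problem's observations."""

    variant: str
    param_name: str
    param_hat: float
    loglik: float
    aic: float
    bic: float
    k: int
    n_obs: int


def smoothed_probs(pmf: RolloutPMF, alpha: float = DEFAULT_ALPHA) -> np.ndarray:
    """Additively smoothed pmf: (count + alpha) / (R + alpha * (G + 1))."""
    counts = np.asarray(pmf.probabilities) * pmf.R
    return (counts + alpha) / (pmf.R + alpha * pmf.support_size)


def loglik(
    observations: Sequence[int], pmf: RolloutPMF, alpha: float = DEFAULT_ALPHA
) -> float:
    """Total smoothed log-likelihood of integer gem counts under ``pmf``."""
    probs = smoothed_probs(pmf, alpha)
    total = 0.0
    for obs in observations:
        if not 0 <= obs < pmf.support_size:
            raise InferenceError(
                f"observation {obs} outside support 0..{pmf.support_size - 1} "
                f"of problem {pmf.problem_id}"
            )
        total += math.log(probs[obs])
    return total


def likelihood_table(
    observations: pd.DataFrame,
    pmfs: Mapping[str, Mapping[int, RolloutPMF]],
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Tidy per-(problem, depth) log-likelihood table.

    ``observations`` needs columns ``problem_id`` and ``gems`` (gems
    collected before the first backtrack); ``pmfs`` maps problem id ->
    depth -> pmf.
    """
    rows = []
    for pid, group in observations.groupby("problem_id", sort=True):
        if pid not in pmfs:
            raise InferenceError(f"no pmfs for problem {pid}")
        obs = group["gems"].to_numpy()
        for depth, pmf in sorted(pmfs[pid].items()):
            if pmf.problem_id != pid:
                raise InferenceError(
                    f"pmf for {pmf.problem_id} filed under problem {pid}"
                )
            rows.append({"problem_id": pid, "depth": depth,
                         "loglik": loglik(obs, pmf, alpha)})
    return pd.DataFrame(rows)


def _loglik_matrix(table: pd.DataFrame) -> tuple[list[str], np.ndarray]:
    wide = table.pivot(index="problem_id", columns="depth", values="loglik")
    wide = wide.reindex(columns=list(DEPTHS))
    if wide.isna().any().any():
        raise InferenceError("likelihood table is incomplete")
    return list(wide.index), wide.to_numpy()


def winner_frequencies(
    table: pd.DataFrame, min_depths: Mapping[str, int]
) -> pd.DataFrame:
    """Row-normalized winner counts per minimum-depth group.

    The winner of a problem is the depth with the highest likelihood;
    exact ties split the problem's unit weight equally.
    """
    pids, L = _loglik_matrix(table)
    groups = sorted({min_depths[p] for p in pids})
    counts = pd.DataFrame(0.0, index=pd.Index(groups, name="min_depth"),
                          columns=pd.Index(list(DEPTHS), name="depth"))
    for pid, row in zip(pids, L):
        winners = np.flatnonzero(row == row.max())
        for w in winners:
            counts.loc[min_depths[pid], DEPTHS[w]] += 1.0 / len(winners)
    return counts.div(counts.sum(axis=1), axis=0)


def rank_analysis(
    table: pd.DataFrame, min_depths: Mapping[str, int]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-problem likelihood ranks (0 = best) and per-model summaries.

    Ranks are a permutation of 0..7 per problem; exact ties are broken in
    favour of the lower depth (the jitter robustness check quantifies how
    much that convention matters). The adaptive model's rank is the rank
    of each problem's own minimum-depth planner.
    """
    pids, L = _loglik_matrix(table)
    order = np.argsort(np.argsort(-L, axis=1, kind="stable"), axis=1, kind="stable")
    records = pd.DataFrame(order, index=pd.Index(pids, name="problem_id"),
                           columns=[f"d{d}" for d in DEPTHS])
    records["adaptive"] = [
        order[i, min_depths[p] - 1] for i, p in enumerate(pids)
    ]
    summary = pd.DataFrame({
        "mean_rank": records.mean(axis=0),
        "median_rank": records.median(axis=0),
    })
    summary.index.name = "model"
    return records, summary


def adaptive_vs_fixed_test(records: pd.DataFrame, fixed_depth: int) -> TestResult:
    """Chi-squared independence test: adaptive vs one fixed-depth model.

    The 2x2 table crosses model (adaptive, fixed-d) with whether the model
    achieved rank 0 on each problem, giving one degree of freedom. A table
    with a zero margin (e.g. neither model ever best) carries no evidence
    of a difference and is reported as statistic 0, p = 1.
    """
    if len(records) < 2:
        raise InferenceError("need at least two problems")
    a = records["adaptive"].to_numpy()
    f = records[f"d{fixed_depth}"].to_numpy()
    tab = np.array([
        [(a == 0).sum(), (a > 0).sum()],
        [(f == 0).sum(), (f > 0).sum()],
    ])
    if (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
        return TestResult(0.0, 1, 1.0, degenerate=True)
    if (tab[0] == tab[1]).all():
        return TestResult(0.0, 1, 1.0)
    chi2, p, df, _ = stats.chi2_contingency(tab, correction=False)
    return TestResult(float(chi2), int(df), float(p))


def _ranks_from_matrix(L: np.ndarray) -> np.ndarray:
    return np.argsort(np.argsort(-L, axis=1, kind="stable"), axis=1, kind="stable")


def _conclusion_holds(
    L: np.ndarray, min_idx: np.ndarray, alpha_level: float
) -> bool:
    """Adaptive model strictly best on mean rank, and every 2x2 test rejects."""
    ranks = _ranks_from_matrix(L)
    adaptive = ranks[np.arange(len(min_idx)), min_idx]
    a_best = (adaptive == 0)
    if not (adaptive.mean() < ranks.mean(axis=0)).all():
        return False
    for d in range(L.shape[1]):
        f_best = ranks[:, d] == 0
        tab = np.array([
            [a_best.sum(), (~a_best).sum()],
            [f_best.sum(), (~f_best).sum()],
        ])
        if (tab.sum(axis=0) == 0).any() or (tab[0] == tab[1]).all():
            return False
        chi2, p, _, _ = stats.chi2_contingency(tab, correction=False)
        if p >= alpha_level:
            return False
    return True


def jitter_robustness(
    table: pd.DataFrame,
    min_depths: Mapping[str, int],
    sigma: Optional[float] = None,
    iterations: int = 10_000,
    rng: Optional[np.random.Generator] = None,
    alpha_level: float = 0.05,
) -> float:
    """Fraction of noise iterations in which adaptive superiority fails.

    Every log-likelihood receives independent N(0, sigma^2) noise, ranks
    and tests are recomputed, and the iteration counts as a rejection if
    the adaptive model is no longer strictly best on mean rank or any
    adaptive-vs-fixed test fails to reject. ``sigma`` defaults to
    1e-6 x median |log-likelihood|, i.e. just enough to break exact ties.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    pids, L = _loglik_matrix(table)
    if sigma is None:
        sigma = 1e-6 * float(np.median(np.abs(L)))
    if sigma <= 0:
        raise InferenceError("sigma must be > 0")
    min_idx = np.array([min_depths[p] - 1 for p in pids])
    rejected = 0
    for _ in range(iterations):
        if not _conclusion_holds(L + rng.normal(0.0, sigma, L.shape), min_idx, alpha_level):
            rejected += 1
    return rejected / iterations


def kl_profile(
    observations: Sequence[int],
    pmfs: Mapping[int, RolloutPMF],
    alpha: float = DEFAULT_ALPHA,
) -> pd.Series:
    """KL(observed || planner) per candidate depth, both smoothed.

    The observed distribution pools all participants' first-plan gem counts
    for one problem; the argmin depth is the KL-based depth estimate.
    """
    depths = sorted(pmfs)
    support = pmfs[depths[0]].support_size
    counts = np.bincount(np.asarray(observations, dtype=int), minlength=support)
    if len(counts) > support:
        raise InferenceError("observation outside pmf support")
    obs = (counts + alpha) / (counts.sum() + alpha * support)
    values = {
        d: float(stats.entropy(obs, smoothed_probs(pmfs[d], alpha)))
        for d in depths
    }
    return pd.Series(values, name="kl").rename_axis("depth")


def fit_noise_params(
    observations: Sequence[int],
    problem: GridProblem,
    depth: int,
    variant: str,
    *,
    R: int = 500,
    seed: int = 0,
    eps_grid: Sequence[float] = DEFAULT_EPS_GRID,
    beta_grid: Sequence[float] = DEFAULT_BETA_GRID,
    alpha: float = DEFAULT_ALPHA,
    cache: Optional[PlanCache] = None,
) -> NoiseFit:
    """Grid-search MLE of epsilon (epsilon-greedy) or beta (softmax).

    Each grid point re-simulates the planner's outcome pmf with R
    instances under a common master seed, then scores the observations.
    AIC = 2k - 2LL and BIC = k ln N - 2LL with k = 1 free parameter
    (k = 0 for the noiseless base planner).
    """
    cache = cache if cache is not None else PlanCache()
    n = len(observations)
    if n == 0:
        raise InferenceError("no observations to fit")

    def score(config: PlannerConfig) -> float:
        return loglik(observations, rollout_pmf(problem, config, R, cache), alpha)

    if variant == "base":
        ll = score(PlannerConfig(depth=depth, seed=seed))
        return NoiseFit("base", "none", float("nan"), ll, -2 * ll,
                        -2 * ll, 0, n)
    if variant == "epsilon_greedy":
        grid = [(e, score(PlannerConfig(depth=depth, variant="epsilon_greedy",
                                        epsilon=float(e), seed=seed)))
                for e in eps_grid]
        name = "epsilon"
    elif variant == "softmax":
        grid = [(b, score(PlannerConfig(depth=depth, variant="softmax",
                                        beta=float(b), seed=seed)))
                for b in beta_grid]
        name = "beta"
    else:
        raise InferenceError(f"cannot fit variant {variant!r}")
    best_param, best_ll = max(grid, key=lambda t: t[1])
    k = 1
    return NoiseFit(variant, name, float(best_param), best_ll,
                    2 * k - 2 * best_ll, k * math.log(n) - 2 * best_ll, k, n)


def epsilon_depth_correlation(
    eps_hats: Sequence[float], min_depths: Sequence[int]
) -> TestResult:
    """Pearson correlation between fitted epsilon and problem min depth."""
    x = np.asarray(eps_hats, dtype=float)
    y = np.asarray(min_depths, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise InferenceError("need >= 3 paired values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return TestResult(float("nan"), len(x) - 2, float("nan"), degenerate=True)
    r, p = stats.pearsonr(x, y)
    return TestResult(float(r), len(x) - 2, float(p))


def summarize_by_cell(
    trials: Iterable,
    problems: Sequence[GridProblem],
    design: Optional[BenchmarkDesign] = None,
) -> pd.DataFrame:
    """Descriptive per-(level, depthID) summary of trial outcomes.

    Reports success probability with its binomial standard error, mean
    move count (selected nodes) and mean number of backtrack episodes
    (maximal runs of unselect events). Cells with no trials are simply
    absent from the table.
    """
    design = design if design is not None else BenchmarkDesign()
    meta = {}
    for p in problems:
        if p.min_depth is None:
            raise InferenceError(f"problem {p.id} is not classified")
        meta[p.id] = (p.level, design.depth_bin_id(p.min_depth))
    rows = []
    for trial in trials:
        if trial.problem_id not in meta:
            raise InferenceError(f"trial references unknown problem {trial.problem_id}")
        level, depth_id = meta[trial.problem_id]
        moves = sum(1 for e in trial.events if e.type == "select")
        backtracks = sum(
            1 for i, e in enumerate(trial.events)
            if e.type == "unselect" and (i == 0 or trial.events[i - 1].type == "select")
        )
        rows.append({"level": level, "depth_id": depth_id,
                     "solved": bool(trial.solved), "moves": moves,
                     "backtracks": backtracks})
    df = pd.DataFrame(rows)
    if df.empty:
        return pd.DataFrame(columns=["level", "depth_id", "n_trials", "success_prob",
                                     "success_se", "mean_moves", "mean_backtracks"])
    out = df.groupby(["level", "depth_id"]).agg(
        n_trials=("solved", "size"),
        success_prob=("solved", "mean"),
        mean_moves=("moves", "mean"),
        mean_backtracks=("backtracks", "mean"),
    ).reset_index()
    out["success_se"] = np.sqrt(
        out["success_prob"] * (1 - out["success_prob"]) / out["n_trials"]
    )
    return out[["level", "depth_id", "n_trials", "success_prob", "success_se",
                "mean_moves", "mean_backtracks"]]
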