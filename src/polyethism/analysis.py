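"""Steady-state analysis: regime classification, age-polyethism
quantification, colony efficiency against a simulated-annealing optimum,
and parameter sweeps over (b, beta, alpha).

A run's steady state is summarised over a trailing *tail window* of its
trajectory.  Engagement means the realised engagement with Task 1: the
action probability ``p`` for the stimulus-coupled model and the trait
``x`` for the pure social-learning model.

Three regimes are distinguished:

* ``regulation_failure`` — the whole colony converges on a single task;
* ``branching_mixed``   — the colony splits into a Task-0 and a Task-1
  group, each containing both age classes;
* ``age_polyethism``    — the colony splits and each task group is
  (almost) exclusively one age class.

*Relative colony efficiency* is the ratio of the tail-average mean payoff
achieved by a run to the best mean payoff attainable by any workforce
allocation (found by simulated annealing) — closely related to the price
of anarchy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd

from .config import RunConfig
from .payoffs import EnvironmentParams
from .rng import derive_seed, substream
from .sl import group_payoff_vector, run_sl
from .srt import run_srt_sl
from .trajectory import Trajectory

__all__ = [
    "REGULATION_FAILURE",
    "BRANCHING_MIXED",
    "AGE_POLYETHISM",
    "RegimeThresholds",
    "SAParams",
    "tail_engagement",
    "engagement_summary",
    "detect_branching",
    "polyethism_index",
    "permutation_pvalue",
    "signed_age_gap",
    "sign_flip_pvalue",
    "classify_regime",
    "branch_age_fractions",
    "mean_payoff",
    "optimal_allocation",
    "achieved_mean_payoff",
    "relative_efficiency",
    "run_model",
    "parameter_sweep",
    "aggregate_regimes",
    "FIG5_PRESET",
    "FIG6_PRESET",
]

REGULATION_FAILURE = "regulation_failure"
BRANCHING_MIXED = "branching_mixed"
AGE_POLYETHISM = "age_polyethism"


@dataclass(frozen=True)
class RegimeThresholds:
    """Classification thresholds: ``lo``/``hi`` bound the "fully on one
    task" bands, ``min_frac`` is the minimum fraction of the colony in each
    band for a split to count as branching, and ``purity`` the majority-age
    fraction each branch needs for the split to count as age polyethism."""

    lo: float = 0.2
    hi: float = 0.8
    min_frac: float = 0.1
    purity: float = 0.9

    def __post_init__(self):
        if not 0.0 <= self.lo < self.hi <= 1.0:
            raise ValueError("thresholds must satisfy 0 <= lo < hi <= 1")
        if not 0.0 < self.min_frac <= 0.5:
            raise ValueError("min_frac must lie in (0, 0.5]")
        if not 0.5 < self.purity <= 1.0:
            raise ValueError("purity must lie in (0.5, 1]")


# ---------------------------------------------------------------------------
# Engagement summaries
# ---------------------------------------------------------------------------

def tail_engagement(traj: Trajectory, tail_fraction: float = 0.2) -> np.ndarray:
    """Per-individual mean engagement over the trailing window of a run."""
    if traj.x.shape[0] == 0:
        raise ValueError("empty trajectory")
    sl = traj.tail_slice(tail_fraction)
    return traj.engagement[sl].mean(axis=0)


def engagement_summary(traj: Trajectory, tail_fraction: float = 0.2) -> dict:
    """Tail-window engagement statistics per age class plus the final-step
    engagement distribution."""
    vals = tail_engagement(traj, tail_fraction)
    final = traj.engagement[-1]
    out: dict = {"final": final, "tail_mean": float(vals.mean())}
    for a, label in ((0, "young"), (1, "old")):
        mask = traj.ages == a
        if mask.any():
            out[f"{label}_mean"] = float(vals[mask].mean())
            out[f"{label}_var"] = float(vals[mask].var())
    return out


def detect_branching(values, lo: float = 0.2, hi: float = 0.8,
                     min_frac: float = 0.1):
    """Detect a two-cluster split of engagement values.

    Returns ``(branched, low_idx, high_idx)`` where the boolean is true iff
    the fractions of values at or below ``lo`` and at or above ``hi`` each
    exceed ``min_frac``.
    """
    if not 0.0 <= lo < hi <= 1.0:
        raise ValueError("need 0 <= lo < hi <= 1")
    vals = np.asarray(values, dtype=float)
    low_idx = np.flatnonzero(vals <= lo)
    high_idx = np.flatnonzero(vals >= hi)
    branched = (low_idx.size > min_frac * vals.size) and (high_idx.size > min_frac * vals.size)
    return branched, low_idx, high_idx


def polyethism_index(traj: Trajectory, tail_fraction: float = 0.2) -> float:
    """Absolute difference between the mean tail engagement of young and of
    old individuals: 0 when ages behave identically, 1 under perfect
    age-based task separation."""
    vals = tail_engagement(traj, tail_fraction)
    young = traj.ages == 0
    old = traj.ages == 1
    if not young.any() or not old.any():
        raise ValueError("both age classes must be present")
    return float(abs(vals[young].mean() - vals[old].mean()))


def _index_from_values(values: np.ndarray, ages: np.ndarray) -> float:
    return float(abs(values[ages == 0].mean() - values[ages == 1].mean()))


def permutation_pvalue(values, ages, n_perm: int = 500,
                       rng: np.random.Generator | None = None) -> float:
    """One-sided p-value of the age-separation statistic against the
    age-label permutation null (is the observed young/old engagement gap
    larger than chance relabelling would produce?)."""
    rng = rng or np.random.default_rng(0)
    values = np.asarray(values, dtype=float)
    ages = np.asarray(ages)
    observed = _index_from_values(values, ages)
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = _index_from_values(values, rng.permutation(ages))
    return float((1 + np.sum(null >= observed)) / (1 + n_perm))


def signed_age_gap(traj: Trajectory, tail_fraction: float = 0.2) -> float:
    """Signed young-minus-old mean tail engagement (the polyethism index
    without the absolute value)."""
    vals = tail_engagement(traj, tail_fraction)
    return float(vals[traj.ages == 0].mean() - vals[traj.ages == 1].mean())


def sign_flip_pvalue(signed_gaps) -> float:
    """Age-label permutation test at the replicate level.

    When costs are age-symmetric the two age *class* labels are
    exchangeable within each replicate even though individuals are not
    (imitation couples individuals within a class), and relabelling flips
    the sign of that replicate's young/old gap.  The null distribution of
    the mean gap is therefore generated by all sign assignments (exact
    enumeration up to 20 replicates, else Monte-Carlo); returns the
    two-sided p-value of the observed mean gap.
    """
    gaps = np.asarray(signed_gaps, dtype=float)
    R = gaps.size
    observed = abs(gaps.mean())
    if R <= 20:
        signs = np.array(list(product((-1.0, 1.0), repeat=R)))
    else:
        signs = np.random.default_rng(0).choice([-1.0, 1.0], size=(20000, R))
    null = np.abs((signs * gaps).mean(axis=1))
    return float(np.mean(null >= observed - 1e-15))


def branch_age_fractions(values, ages, thresholds: RegimeThresholds = RegimeThresholds()):
    """Old-individual fraction in the Task-0 (low-engagement) and Task-1
    (high-engagement) branches; NaN for an absent branch."""
    _, low_idx, high_idx = detect_branching(values, thresholds.lo, thresholds.hi,
                                            thresholds.min_frac)
    ages = np.asarray(ages)
    frac = lambda idx: float(ages[idx].mean()) if idx.size else float("nan")
    return frac(low_idx), frac(high_idx)


def classify_regime(values, ages, thresholds: RegimeThresholds = RegimeThresholds()) -> str:
    """Assign a regime label to a steady-state engagement profile.

    ``regulation_failure`` when the colony mean sits in an extreme band and
    there is no two-cluster split; ``age_polyethism`` when the colony splits
    and each branch's majority age class reaches the purity threshold;
    ``branching_mixed`` otherwise.
    """
    vals = np.asarray(values, dtype=float)
    ages = np.asarray(ages)
    branched, low_idx, high_idx = detect_branching(vals, thresholds.lo, thresholds.hi,
                                                   thresholds.min_frac)
    mean = float(vals.mean())
    if not branched and (mean <= thresholds.lo or mean >= thresholds.hi):
        return REGULATION_FAILURE
    if branched:
        pure = True
        for idx in (low_idx, high_idx):
            old_frac = float(ages[idx].mean())
            if max(old_frac, 1.0 - old_frac) < thresholds.purity:
                pure = False
        if pure:
            return AGE_POLYETHISM
    return BRANCHING_MIXED


# ---------------------------------------------------------------------------
# Optimal allocation via simulated annealing, relative efficiency
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SAParams:
    """Simulated-annealing settings: geometric cooling ``t <- cooling * t``
    every ``cooling_interval`` iterations from ``t0``, single-coordinate
    Gaussian proposals clipped to [0, 1], Metropolis acceptance.  Proposals
    mix two widths — half the moves use ``proposal_sd`` (basin hopping),
    half use ``proposal_sd_fine`` (local refinement) — so the optimum is
    both found and polished within one run."""

    iterations: int = 40000
    t0: float = 1.0
    cooling: float = 0.95
    cooling_interval: int = 100
    proposal_sd: float = 0.1
    proposal_sd_fine: float = 0.005
    seed: int = 0

    def __post_init__(self):
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if not 0.0 < self.cooling < 1.0:
            raise ValueError("cooling factor must lie in (0, 1)")
        if self.t0 <= 0 or self.proposal_sd <= 0 or self.cooling_interval < 1:
            raise ValueError("t0, proposal_sd and cooling_interval must be positive")
        if not 0 < self.proposal_sd_fine <= self.proposal_sd:
            raise ValueError("proposal_sd_fine must lie in (0, proposal_sd]")


def mean_payoff(x: np.ndarray, ages: np.ndarray, partition: np.ndarray,
                env: EnvironmentParams) -> float:
    """Population mean payoff of a deterministic engagement allocation
    under a fixed game partition."""
    return float(group_payoff_vector(np.asarray(x, float), np.asarray(ages), partition, env).mean())


def _default_partition(N: int, n: int) -> np.ndarray:
    return np.arange(N).reshape(N // n, n)


def optimal_allocation(env: EnvironmentParams, ages, sa: SAParams = SAParams(),
                       partition: np.ndarray | None = None, objective=None):
    """Best workforce allocation found by simulated annealing.

    Maximises the population mean payoff under a fixed game partition
    (removing partition noise from the benchmark), or any injected
    ``objective(x) -> float``.  Returns ``(best_x, best_value, history)``
    where ``history`` is the non-decreasing best-so-far value per iteration.
    """
    ages = np.asarray(ages)
    N = ages.shape[0]
    if partition is None:
        partition = _default_partition(N, env.n)
    if objective is None:
        objective = lambda x: mean_payoff(x, ages, partition, env)

    rng = substream(sa.seed, "annealing")
    current = np.full(N, 0.5)
    f_cur = objective(current)
    best = current.copy()
    f_best = f_cur
    temp = sa.t0
    history = np.empty(sa.iterations)

    for it in range(sa.iterations):
        j = int(rng.integers(N))
        sd = sa.proposal_sd if rng.random() < 0.5 else sa.proposal_sd_fine
        proposal = current.copy()
        proposal[j] = min(1.0, max(0.0, proposal[j] + rng.normal(0.0, sd)))
        f_prop = objective(proposal)
        delta = f_prop - f_cur
        if delta >= 0 or rng.random() < math.exp(delta / temp):
            current, f_cur = proposal, f_prop
            if f_cur > f_best:
                best, f_best = current.copy(), f_cur
        history[it] = f_best
        if (it + 1) % sa.cooling_interval == 0:
            temp *= sa.cooling

    return best, float(f_best), history


def achieved_mean_payoff(traj: Trajectory, tail_fraction: float = 0.2) -> float:
    """Tail-average of the per-generation population mean payoff."""
    if traj.payoffs.shape[0] == 0:
        raise ValueError("trajectory has no recorded payoffs")
    rows = traj.payoffs.shape[0]
    start = rows - max(1, int(round(tail_fraction * rows)))
    return float(traj.payoffs[start:].mean())


def relative_efficiency(traj: Trajectory, optimal_payoff: float,
                        tail_fraction: float = 0.2) -> float:
    """Achieved ÷ optimal mean payoff; NaN (undefined) when the optimum is
    not strictly positive."""
    if not optimal_payoff > 0:
        return float("nan")
    return achieved_mean_payoff(traj, tail_fraction) / optimal_payoff


# ---------------------------------------------------------------------------
# Running models and sweeping parameters
# ---------------------------------------------------------------------------

def run_model(cfg: RunConfig) -> Trajectory:
    """Dispatch to the engine selected by ``cfg.run.model``."""
    return run_srt_sl(cfg) if cfg.run.model == "srt" else run_sl(cfg)


def analyse_run(traj: Trajectory, thresholds: RegimeThresholds = RegimeThresholds(),
                tail_fraction: float | None = None,
                sa: SAParams | None = None, compute_efficiency: bool = True) -> dict:
    """Classify one run and compute its summary statistics (and, optionally,
    its relative efficiency against a freshly annealed optimum)."""
    tf = tail_fraction if tail_fraction is not None else traj.config.get(
        "run", {}).get("tail_fraction", 0.2)
    vals = tail_engagement(traj, tf)
    regime = classify_regime(vals, traj.ages, thresholds)
    low_old, high_old = branch_age_fractions(vals, traj.ages, thresholds)
    out = {
        "regime": regime,
        "polyethism_index": _index_from_values(vals, traj.ages),
        "mean_engagement": float(vals.mean()),
        "task0_branch_old_frac": low_old,
        "task1_branch_old_frac": high_old,
    }
    if compute_efficiency:
        env = EnvironmentParams(**traj.config["environment"])
        sa = sa or SAParams(seed=derive_seed(traj.seed or 0, 10**6))
        _, f_best, _ = optimal_allocation(env, traj.ages, sa)
        out["optimal_payoff"] = f_best
        out["efficiency"] = relative_efficiency(traj, f_best, tf)
    return out


def parameter_sweep(b_grid, beta_grid, alphas, replicates: int,
                    base_config: RunConfig, master_seed: int | None = None,
                    thresholds: RegimeThresholds = RegimeThresholds(),
                    compute_efficiency: bool = True,
                    sa: SAParams | None = None) -> pd.DataFrame:
    """Run the configured model over the (b, beta, alpha) grid.

    Every cell runs ``replicates`` independent seeds derived from the
    master seed by a counter; each row records its own seed, regime label,
    polyethism index and (optionally) relative efficiency.  A failed cell
    is recorded with its error message and the sweep continues.
    """
    if len(b_grid) == 0 or len(beta_grid) == 0 or len(alphas) == 0:
        raise ValueError("parameter grids must be non-empty")
    master_seed = base_config.seed if master_seed is None else master_seed
    rows = []
    counter = 0
    for alpha in alphas:
        for b in b_grid:
            for beta in beta_grid:
                for rep in range(replicates):
                    seed = derive_seed(master_seed, counter)
                    counter += 1
                    row = {"b": float(b), "beta": float(beta), "alpha": float(alpha),
                           "rep": rep, "seed": seed}
                    try:
                        cfg = (base_config
                               .replace_fields("environment", b=float(b), beta=float(beta))
                               .replace_fields("learning", alpha=float(alpha))
                               .replace(seed=seed))
                        traj = run_model(cfg)
                        cell_sa = sa if sa is None else SAParams(
                            **{**sa.__dict__, "seed": derive_seed(seed, 10**6)})
                        res = analyse_run(traj, thresholds,
                                          tail_fraction=cfg.run.tail_fraction,
                                          sa=cell_sa,
                                          compute_efficiency=compute_efficiency)
                        row.update(res)
                        row["error"] = ""
                    except Exception as exc:  # record and continue
                        row["error"] = f"{type(exc).__name__}: {exc}"
                    rows.append(row)
    return pd.DataFrame(rows)


def aggregate_regimes(sweep: pd.DataFrame) -> pd.DataFrame:
    """Replicate-aggregated view per (b, beta, alpha) cell: modal regime
    label (ties flagged), mean polyethism index and mean efficiency."""
    def _agg(group: pd.DataFrame) -> pd.Series:
        counts = group["regime"].value_counts()
        top = counts.max()
        modal = sorted(counts[counts == top].index)
        return pd.Series({
            "regime": modal[0],
            "regime_tie": len(modal) > 1,
            "n_modal": int(top),
            "polyethism_index": group["polyethism_index"].mean(),
            "efficiency": group["efficiency"].mean() if "efficiency" in group else float("nan"),
            "replicates": len(group),
        })
    ok = sweep[sweep["error"] == ""] if "error" in sweep else sweep
    return ok.groupby(["b", "beta", "alpha"]).apply(_agg, include_groups=False).reset_index()


# Canned environmental settings matching the published phenomenology panels:
# four (b, beta) points at intermediate cross-age recruitment, and the
# cross-age recruitment limits at fixed abundance.
FIG5_PRESET = {"alpha": 0.5, "points": [(2.0, 0.45), (20.0, 0.0), (20.0, 0.25), (20.0, 0.75)]}
FIG6_PRESET = {"b": 20.0, "betas": [0.0, 0.25, 0.75], "alphas": [0.0, 1.0]}
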