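"""Pure Social Learning (SL) engine.

Each generation: the population is randomly partitioned into K = N/n
interaction groups; everyone earns a payoff from the colony game; every
individual then synchronously picks a cultural parent to imitate — with
probability increasing in the parent's payoff and decreasing in age
dissimilarity — and finally traits undergo rare Gaussian mutation, clipped
to [0, 1].  Ages never change: the model describes the fast behavioural
dynamics induced by a fixed age structure, not the ageing process itself.

The imitation weight of potential parent i for a focal individual j is

    w_i ∝ exp(-omega * alpha * |a_i - a_j|) * exp(Pi_i),

normalised over the whole population (self included; self-imitation is a
no-op).  With ``alpha = 0`` this is exactly a softmax of payoffs — age is
ignored; with ``omega * alpha`` large, cross-age imitation is suppressed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import LearningParams, RunConfig
from .payoffs import EnvironmentParams, benefit_task0, benefit_task1, total_cost
from .rng import substream
from .trajectory import Trajectory

__all__ = [
    "Population",
    "partition_population",
    "group_payoff_vector",
    "compute_payoffs",
    "imitation_weights",
    "imitation_distribution",
    "social_learning_step",
    "mutation_step",
    "initial_population",
    "run_sl",
]


@dataclass
class Population:
    """Ordered colony state: trait vector ``x`` (engagement with Task 1)
    and fixed age-class vector ``ages`` (0 young, 1 old)."""

    x: np.ndarray
    ages: np.ndarray

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.ages = np.asarray(self.ages, dtype=np.int8)
        if self.x.shape != self.ages.shape or self.x.ndim != 1:
            raise ValueError("trait and age vectors must be 1-D and equal-length")
        if np.any(self.x < 0) or np.any(self.x > 1):
            raise ValueError("traits must lie in [0, 1]")
        if not np.all((self.ages == 0) | (self.ages == 1)):
            raise ValueError("ages must be 0 (young) or 1 (old)")

    @property
    def N(self) -> int:
        return self.x.shape[0]


def initial_population(cfg: RunConfig, rng: np.random.Generator) -> Population:
    """Build the starting colony: N/2 young then N/2 old, all at trait
    ``x0`` (or uniform-random traits if configured)."""
    N = cfg.run.N
    ages = np.zeros(N, dtype=np.int8)
    ages[N // 2:] = 1
    if cfg.run.init == "uniform":
        x = rng.random(N)
    else:
        x = np.full(N, float(cfg.run.x0))
    return Population(x=x, ages=ages)


def partition_population(N: int, n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniformly random partition of ``range(N)`` into K = N/n disjoint
    groups of size ``n``, returned as an integer array of shape (K, n)."""
    if N % n != 0:
        raise ValueError(f"group size n={n} must divide population size N={N}")
    return rng.permutation(N).reshape(N // n, n)


def group_payoff_vector(x: np.ndarray, ages: np.ndarray, partition: np.ndarray,
                        env: EnvironmentParams) -> np.ndarray:
    """Vectorised payoffs for arbitrary engagement values ``x`` (traits in
    the SL engine, action probabilities in the stimulus-coupled engine)."""
    gx = x[partition]                          # (K, n)
    e1 = gx.sum(axis=1)
    e0 = env.n - e1
    shared = (benefit_task0(e0, env) * benefit_task1(e1, env)) / env.n  # (K,)
    payoffs = np.empty_like(x)
    payoffs[partition] = shared[:, None]
    payoffs -= total_cost(x, ages, env)
    return payoffs


def compute_payoffs(pop: Population, partition: np.ndarray, env: EnvironmentParams) -> np.ndarray:
    """Payoff vector of length N: each individual's shared group benefit
    minus its individual, age-dependent cost."""
    if np.sort(partition.ravel()).tolist() != list(range(pop.N)):
        raise ValueError("partition must cover every individual exactly once")
    if partition.shape[1] != env.n:
        raise ValueError(f"partition groups must have size n={env.n}")
    return group_payoff_vector(pop.x, pop.ages, partition, env)


def imitation_weights(ages: np.ndarray, payoffs: np.ndarray, focal_age: int,
                      lp: LearningParams) -> np.ndarray:
    """Normalised imitation distribution over all N potential parents for a
    focal individual of the given age class.

    Invariant to adding any constant to all payoffs (the maximum is
    subtracted inside the exponential to guard against overflow).
    """
    if not np.all(np.isfinite(payoffs)):
        raise ValueError("payoffs must be finite")
    logw = payoffs - payoffs.max()
    logw = logw - lp.omega * lp.alpha * np.abs(ages - focal_age)
    w = np.exp(logw)
    return w / w.sum()


def imitation_distribution(pop: Population, payoffs: np.ndarray, focal: int,
                           lp: LearningParams) -> np.ndarray:
    """Imitation distribution for focal individual ``focal`` (see
    :func:`imitation_weights`; it depends on the focal only through its
    age class)."""
    return imitation_weights(pop.ages, payoffs, int(pop.ages[focal]), lp)


def social_learning_step(pop: Population, payoffs: np.ndarray, lp: LearningParams,
                         rng: np.random.Generator) -> Population:
    """Synchronous imitation: every individual independently samples a
    parent from its imitation distribution and adopts that parent's
    *previous-step* trait.  Ages never change."""
    # only two distinct distributions exist (one per focal age class)
    cdfs = {a: np.cumsum(imitation_weights(pop.ages, payoffs, a, lp)) for a in (0, 1)}
    u = rng.random(pop.N)
    parents = np.empty(pop.N, dtype=np.int64)
    for a in (0, 1):
        mask = pop.ages == a
        parents[mask] = np.searchsorted(cdfs[a], u[mask], side="left")
    np.minimum(parents, pop.N - 1, out=parents)  # guard cdf round-off at 1.0
    return Population(x=pop.x[parents], ages=pop.ages)


def mutation_step(pop: Population, lp: LearningParams, rng: np.random.Generator) -> Population:
    """Behavioural exploration: with probability ``mu`` each trait is
    replaced by a Gaussian perturbation of itself, clipped to [0, 1]."""
    mask = rng.random(pop.N) < lp.mu
    proposals = rng.normal(pop.x, lp.sigma)
    x = np.where(mask, np.clip(proposals, 0.0, 1.0), pop.x)
    return Population(x=x, ages=pop.ages)


def run_sl(cfg: RunConfig) -> Trajectory:
    """Run the pure social-learning model for ``T`` generations.

    Each generation: (re)partition into games, compute payoffs, imitate,
    mutate.  By default the partition is redrawn every generation.  The
    returned trajectory holds the initial condition plus every updated
    generation, with the payoff vector earned at each step.
    """
    env, lp, run, seed = cfg.environment, cfg.learning, cfg.run, cfg.seed
    repartition = run.repartition or "every_step"
    part_rng = substream(seed, "partition")
    imit_rng = substream(seed, "imitation")
    mut_rng = substream(seed, "mutation")
    init_rng = substream(seed, "init")

    pop = initial_population(cfg, init_rng)
    T, N = run.T, run.N
    xs = np.empty((T + 1, N))
    payoffs = np.empty((T, N))
    xs[0] = pop.x

    partition = partition_population(N, env.n, part_rng)
    for t in range(1, T + 1):
        if repartition == "every_step" and t > 1:
            partition = partition_population(N, env.n, part_rng)
        pi = group_payoff_vector(pop.x, pop.ages, partition, env)
        pop = social_learning_step(pop, pi, lp, imit_rng)
        pop = mutation_step(pop, lp, mut_rng)
        payoffs[t - 1] = pi
        xs[t] = pop.x

    return Trajectory(model="sl", x=xs, ages=pop.ages, payoffs=payoffs,
                      config=cfg.to_dict(), seed=seed)
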