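"""Stimulus-Response Threshold Social Learning (SRT-SL) engine.

This engine extends the pure social-learning model with stigmergy: each
task carries a colony-wide stimulus level that rises when the task is
under-serviced, and individual traits are reinterpreted as response
*thresholds* rather than engagement probabilities.  The probability that
individual ``i`` performs Task 1 is a sigmoid of its threshold and the
stimulus difference,

    p_i = 1 - 1 / (1 + exp(-gamma * [(x_i - 0.5) + (S0 - S1)])),

so a high foraging stimulus ``S0`` pushes everyone toward Task 0 and a
high homeostatic stimulus ``S1`` toward Task 1.  Stimuli follow deficit
dynamics: ``S0`` grows in proportion to the shortfall of the aggregate
foraging benefit below the colony demand ``B0min`` and ``S1`` in proportion
to the shortfall of the aggregate homeostatic benefit below its attainable
maximum ``B1max``; both decay and are confined to [0, 1].

One generation follows a fixed order: payoffs are earned from the
*previous* step's action probabilities (costs too are paid on realised
effort ``p``, not on the threshold); thresholds are updated by imitation
and mutation; stimuli are updated from the previous step's collective
action; finally action probabilities are recomputed from the new
thresholds and new stimuli.  Interaction groups are drawn once at the
start and stay fixed (switchable to per-step repartition).
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

from .config import RunConfig, StimulusParams, resolve_stimulus_params
from .payoffs import EnvironmentParams, benefit_task0, benefit_task1
from .rng import substream
from .sl import (
    Population,
    group_payoff_vector,
    initial_population,
    mutation_step,
    partition_population,
    social_learning_step,
)
from .trajectory import Trajectory

__all__ = [
    "action_probability",
    "stimulus_increment",
    "srt_generation",
    "run_srt_sl",
]


def action_probability(x, S0: float, S1: float, gamma: float):
    """Probability of adopting Task 1 given threshold ``x`` and stimulus
    levels: strictly decreasing in ``x``, strictly increasing in
    ``S1 - S0``.  Overflow-safe via the logistic ``expit``."""
    z = gamma * ((np.asarray(x, dtype=float) - 0.5) + (S0 - S1))
    out = expit(-z)
    return out.item() if out.ndim == 0 else out


def stimulus_increment(S0: float, S1: float, group_probs: np.ndarray,
                       env: EnvironmentParams, sp: StimulusParams) -> tuple[float, float]:
    """Deficit-driven stimulus increments ``(dS0, dS1)``.

    ``group_probs`` holds the per-group action probabilities, shape (K, n).
    The foraging stimulus grows with the (non-negative) shortfall of the
    total foraging benefit — computed on the Task-0 effort ``sum(1 - p)``
    of each group — below the demand ``B0min``; the homeostatic stimulus
    grows with the shortfall of the total Task-1 benefit below ``B1max``.
    ``sp`` must be fully resolved (no ``None`` gains or demands).
    """
    probs = np.asarray(group_probs, dtype=float)
    if probs.ndim != 2 or probs.shape[1] != env.n:
        raise ValueError(f"group_probs must have shape (K, n={env.n}), got {probs.shape}")
    if np.any(probs < 0) or np.any(probs > 1):
        raise ValueError("action probabilities must lie in [0, 1]")
    if sp.lambda1 is None or sp.phi1 is None or sp.B0min is None or sp.B1max is None:
        raise ValueError("stimulus params must be resolved (see resolve_stimulus_params)")
    e1 = probs.sum(axis=1)
    e0 = env.n - e1
    tot_b0 = float(np.sum(benefit_task0(e0, env)))
    tot_b1 = float(np.sum(benefit_task1(e1, env)))
    dS0 = sp.lambda1 * max(0.0, sp.B0min - tot_b0) - sp.lambda2 * S0
    dS1 = sp.phi1 * (sp.B1max - tot_b1) - sp.phi2 * S1
    return dS0, dS1


def srt_generation(pop: Population, partition: np.ndarray, S: tuple[float, float],
                   env: EnvironmentParams, lp, sp: StimulusParams,
                   imit_rng: np.random.Generator, mut_rng: np.random.Generator):
    """Advance one generation; returns ``(pop', S', diagnostics)``.

    The previous step's action probabilities are recomputed from the
    incoming thresholds and stimuli (they are a deterministic function of
    both), then the update proceeds in the fixed order: payoffs from
    previous action, imitation of thresholds, mutation, stimulus update,
    new action probabilities.
    """
    S0, S1 = S
    p_prev = action_probability(pop.x, S0, S1, sp.gamma)
    payoffs = group_payoff_vector(p_prev, pop.ages, partition, env)
    pop = social_learning_step(pop, payoffs, lp, imit_rng)
    pop = mutation_step(pop, lp, mut_rng)
    dS0, dS1 = stimulus_increment(S0, S1, p_prev[partition], env, sp)
    S_new = (float(np.clip(S0 + dS0, 0.0, 1.0)), float(np.clip(S1 + dS1, 0.0, 1.0)))
    p_new = action_probability(pop.x, S_new[0], S_new[1], sp.gamma)
    diagnostics = {"payoffs": payoffs, "p_prev": p_prev, "p_new": p_new}
    return pop, S_new, diagnostics


def run_srt_sl(cfg: RunConfig) -> Trajectory:
    """Run the stimulus-coupled model for ``T`` generations from the fixed
    initial profile ``(x0, S0_0, S1_0)``; records thresholds, action
    probabilities, stimuli and payoffs at every step."""
    env, lp, run, seed = cfg.environment, cfg.learning, cfg.run, cfg.seed
    repartition = run.repartition or "fixed"
    K = run.N // env.n
    sp = resolve_stimulus_params(cfg.stimulus, env, K)

    part_rng = substream(seed, "partition")
    imit_rng = substream(seed, "imitation")
    mut_rng = substream(seed, "mutation")
    init_rng = substream(seed, "init")

    pop = initial_population(cfg, init_rng)
    T, N = run.T, run.N
    xs = np.empty((T + 1, N))
    ps = np.empty((T + 1, N))
    stim = np.empty((T + 1, 2))
    payoffs = np.empty((T, N))

    S = (float(sp.S0_0), float(sp.S1_0))
    xs[0] = pop.x
    ps[0] = action_probability(pop.x, S[0], S[1], sp.gamma)
    stim[0] = S

    partition = partition_population(N, env.n, part_rng)
    for t in range(1, T + 1):
        if repartition == "every_step" and t > 1:
            partition = partition_population(N, env.n, part_rng)
        pop, S, diag = srt_generation(pop, partition, S, env, lp, sp, imit_rng, mut_rng)
        xs[t] = pop.x
        ps[t] = diag["p_new"]
        stim[t] = S
        payoffs[t - 1] = diag["payoffs"]

    return Trajectory(model="srt", x=xs, ages=pop.ages, payoffs=payoffs,
                      p=ps, stimuli=stim, config=cfg.to_dict(), seed=seed)
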