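"""Cost, benefit and payoff functions for the two-task colony game.

The colony faces two prototypical tasks:

* **Task 0** — an out-of-nest *maximising* task (foraging): its benefit
  grows with the collective effort invested, and it becomes cheaper with
  practice and with age.
* **Task 1** — an in-nest *homeostatic* task (thermoregulation): it has an
  interior optimum; over-investment yields no further benefit and can even
  be harmful.

Conventions used throughout the package:

* the trait ``x`` in ``[0, 1]`` is an individual's engagement with Task 1,
  so ``1 - x`` is its engagement with Task 0 (foraging);
* the age class ``a`` is 0 for *young* and 1 for *old* individuals.

Three environmental parameters shape the game: ``b`` is the benefit/cost
ratio of foraging (large ``b`` = abundant environment), ``r`` is the cost
ratio of Task 1 to Task 0, and ``beta`` is the extra foraging cost borne
by young individuals (``beta = 0`` makes the tasks age-symmetric).

The exact algebraic shapes of the aggregate benefit of each task and of the
Task-1 cost are configurable: the defaults are a linear foraging benefit,
a concave (parabolic) homeostatic benefit with its peak at half the group
effort, and a linear Task-1 cost.  Alternative shapes can be registered or
passed as callables on :class:`EnvironmentParams`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Union

import numpy as np

__all__ = [
    "YOUNG",
    "OLD",
    "EnvironmentParams",
    "ClassicThresholdParams",
    "classic_response_probability",
    "classic_threshold_update",
    "cost_task0",
    "cost_task1",
    "total_cost",
    "benefit_task0",
    "benefit_task1",
    "group_benefit",
    "individual_payoff",
]

YOUNG = 0
OLD = 1

FormSpec = Union[str, Callable]


def _validate_age(a) -> None:
    arr = np.asarray(a)
    if not np.all((arr == 0) | (arr == 1)):
        raise ValueError(f"age class must be 0 (young) or 1 (old), got {a!r}")


def _validate_unit(x, name: str) -> None:
    arr = np.asarray(x, dtype=float)
    if np.any(arr < 0.0) or np.any(arr > 1.0):
        raise ValueError(f"{name} must lie in [0, 1], got {x!r}")


# ---------------------------------------------------------------------------
# Functional-form registries.  Aggregate benefits take the collective effort
# invested in the task (a value in [0, n]); individual Task-1 cost takes the
# individual engagement x in [0, 1].
# ---------------------------------------------------------------------------

def _benefit0_linear(e0, env: "EnvironmentParams"):
    return env.b * e0


def _benefit1_concave_parabola(e1, env: "EnvironmentParams"):
    u = np.asarray(e1, dtype=float) / env.n
    return 4.0 * u * (1.0 - u)


def _cost1_linear(x, env: "EnvironmentParams"):
    return env.r * np.asarray(x, dtype=float)


BENEFIT0_FORMS: dict[str, Callable] = {"linear": _benefit0_linear}
BENEFIT1_FORMS: dict[str, Callable] = {"concave_parabola": _benefit1_concave_parabola}
COST1_FORMS: dict[str, Callable] = {"linear": _cost1_linear}


def _resolve(form: FormSpec, registry: dict[str, Callable], kind: str) -> Callable:
    if callable(form):
        return form
    try:
        return registry[form]
    except KeyError:
        raise ValueError(
            f"unknown {kind} form {form!r}; known: {sorted(registry)}"
        ) from None


@dataclass(frozen=True)
class EnvironmentParams:
    """Ecology and task-cost geometry of the colony game.

    Parameters
    ----------
    b : float
        Benefit/cost ratio of Task 0 (foraging).  Larger values mean an
        abundant environment; small values mean scarcity.
    r : float
        Cost ratio of Task 1 relative to Task 0.
    beta : float
        Age cost differential of Task 0: young individuals pay a factor
        ``exp(beta)`` more for foraging effort.  ``beta = 0`` removes any
        age asymmetry.
    n : int
        Interaction group (game) size.
    """

    b: float = 20.0
    r: float = 1.0
    beta: float = 0.0
    n: int = 10
    benefit0: FormSpec = "linear"
    benefit1: FormSpec = "concave_parabola"
    cost1: FormSpec = "linear"

    def __post_init__(self):
        if self.b <= 0:
            raise ValueError(f"environment.b must be > 0, got {self.b}")
        if self.r <= 0:
            raise ValueError(f"environment.r must be > 0, got {self.r}")
        if self.beta < 0:
            raise ValueError(f"environment.beta must be >= 0, got {self.beta}")
        if int(self.n) != self.n or self.n < 1:
            raise ValueError(f"environment.n must be a positive integer, got {self.n}")
        object.__setattr__(self, "n", int(self.n))
        # fail fast on unknown functional forms
        _resolve(self.benefit0, BENEFIT0_FORMS, "benefit0")
        _resolve(self.benefit1, BENEFIT1_FORMS, "benefit1")
        _resolve(self.cost1, COST1_FORMS, "cost1")


@dataclass(frozen=True)
class ClassicThresholdParams:
    """Parameters of the classic reinforced response-threshold model:
    ``theta`` is the internal threshold, ``xi`` and ``phi`` the speeds of
    learning (threshold decrease on task execution) and forgetting."""

    theta: float = 0.5
    xi: float = 0.1
    phi: float = 0.1

    def __post_init__(self):
        for name in ("theta", "xi", "phi"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


# ---------------------------------------------------------------------------
# Classic response-threshold reference operations (baseline comparison only)
# ---------------------------------------------------------------------------

def classic_response_probability(s, theta):
    """Sigmoid response probability ``s^2 / (s^2 + theta^2)`` of engaging a
    task at stimulus intensity ``s`` given internal threshold ``theta``."""
    s_arr = np.asarray(s, dtype=float)
    th = np.asarray(theta, dtype=float)
    if np.any(s_arr < 0) or np.any(th < 0):
        raise ValueError("stimulus and threshold must be non-negative")
    if np.any((s_arr == 0) & (th == 0)):
        raise ValueError("response probability undefined at s = theta = 0")
    out = s_arr**2 / (s_arr**2 + th**2)
    return out.item() if np.isscalar(s) and np.isscalar(theta) else out


def classic_threshold_update(theta: float, performed: bool, params: ClassicThresholdParams) -> float:
    """Reinforcement update of the classic threshold: learning lowers it by
    ``xi`` when the task was performed, forgetting raises it by ``phi``
    otherwise.  Clipped below at zero (a threshold is a stimulus comparator;
    negative values are meaningless)."""
    new = theta - params.xi if performed else theta + params.phi
    return max(0.0, new)


# ---------------------------------------------------------------------------
# Costs
# ---------------------------------------------------------------------------

def cost_task0(x, a, beta: float):
    """Individual cost of foraging effort ``1 - x``.

    The shape ``-(1-x)^2 + 2(1-x)`` is marginally decreasing in effort
    (foraging gets easier with practice), and the factor ``exp(beta (1-a))``
    scales it up for young individuals (``a = 0``).  Old individuals
    (``a = 1``) are unaffected by ``beta``.
    """
    _validate_unit(x, "engagement x")
    _validate_age(a)
    x_arr = np.asarray(x, dtype=float)
    a_arr = np.asarray(a, dtype=float)
    u = 1.0 - x_arr
    base = -(u**2) + 2.0 * u
    out = base * np.exp(beta * (1.0 - a_arr))
    return out.item() if out.ndim == 0 else out


def cost_task1(x, env: EnvironmentParams):
    """Individual cost of Task-1 engagement ``x`` (default: linear, ``r x``)."""
    _validate_unit(x, "engagement x")
    out = np.asarray(_resolve(env.cost1, COST1_FORMS, "cost1")(x, env), dtype=float)
    return out.item() if out.ndim == 0 else out


def total_cost(x, a, env: EnvironmentParams):
    """Additive total cost of splitting effort between the two tasks."""
    return cost_task0(x, a, env.beta) + cost_task1(x, env)


# ---------------------------------------------------------------------------
# Benefits and payoff
# ---------------------------------------------------------------------------

def _validate_effort(e, env: EnvironmentParams, name: str) -> None:
    arr = np.asarray(e, dtype=float)
    if np.any(arr < 0) or np.any(arr > env.n):
        raise ValueError(f"{name} must lie in [0, n={env.n}], got {e!r}")


def benefit_task0(e0, env: EnvironmentParams):
    """Aggregate foraging benefit of collective Task-0 effort ``e0`` in
    ``[0, n]`` (default: linear, ``b e0``)."""
    _validate_effort(e0, env, "task-0 effort")
    out = np.asarray(_resolve(env.benefit0, BENEFIT0_FORMS, "benefit0")(e0, env), dtype=float)
    return out.item() if out.ndim == 0 else out


def benefit_task1(e1, env: EnvironmentParams):
    """Aggregate homeostatic benefit of collective Task-1 effort ``e1`` in
    ``[0, n]`` (default: concave parabola with unit peak at ``n/2``)."""
    _validate_effort(e1, env, "task-1 effort")
    out = np.asarray(_resolve(env.benefit1, BENEFIT1_FORMS, "benefit1")(e1, env), dtype=float)
    return out.item() if out.ndim == 0 else out


def group_benefit(engagements, env: EnvironmentParams):
    """Shared per-capita benefit of one interaction group.

    Both tasks must be serviced for the colony to function, so the group
    benefit couples them multiplicatively:
    ``(1/n) * B0(sum(1 - x_j)) * B1(sum(x_j))``.
    Every group member receives the same share; only collective effort —
    never individual age — enters the benefit.
    """
    xs = np.asarray(engagements, dtype=float)
    if xs.shape != (env.n,):
        raise ValueError(
            f"engagement vector must have length n={env.n}, got shape {xs.shape}"
        )
    _validate_unit(xs, "engagements")
    e1 = float(xs.sum())
    e0 = env.n - e1
    return (1.0 / env.n) * benefit_task0(e0, env) * benefit_task1(e1, env)


def individual_payoff(x: float, a: int, engagements, env: EnvironmentParams) -> float:
    """Payoff of one group member: its share of the collective benefit minus
    its own (age-dependent) task cost.  ``x`` must appear in ``engagements``."""
    xs = np.asarray(engagements, dtype=float)
    if not np.any(np.isclose(xs, x, rtol=0.0, atol=1e-12)):
        raise ValueError("focal engagement x must appear in the group's engagement vector")
    return group_benefit(xs, env) - total_cost(x, a, env)
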