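"""Adaptive-dynamics cross-check of the simulation.

Treats the colony game in the standard adaptive-dynamics limit — an
effectively infinite population, small rare mutations — and asks what a
*monomorphic-per-age-class* resident population ``(x_young, x_old)``
selects for.  The invasion fitness of a rare mutant is its expected payoff
in groups otherwise composed of residents (group age composition drawn
from the even young/old mix) minus the expected payoff of a same-age
resident.  Zeros of the selection gradient are *singular strategies*;
their second-order properties separate end points of the dynamics (ESS)
from *branching points*, where the population splits into two coexisting
trait clusters — the analytical signature of specialisation in the
simulation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import product

import numpy as np
from scipy.special import comb

from .payoffs import EnvironmentParams, benefit_task0, benefit_task1, total_cost

__all__ = [
    "ResidentState",
    "invasion_fitness",
    "selection_gradient",
    "classify_singular_point",
    "find_singular_strategies",
    "boundary_analysis",
]

_EPS_BOUNDARY = 1e-4


@dataclass(frozen=True)
class ResidentState:
    """Monomorphic resident trait per age class."""

    x_young: float
    x_old: float

    def __post_init__(self):
        for name in ("x_young", "x_old"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")

    def trait(self, age: int) -> float:
        return self.x_young if age == 0 else self.x_old


def _age_mix_weights(m: int, rng: np.random.Generator | None = None,
                     mc_samples: int = 20000):
    """Distribution of the number of young among ``m`` random residents
    under the even age mix: exact binomial enumeration for m <= 12,
    Monte-Carlo beyond."""
    if m <= 12 or rng is None:
        ks = np.arange(m + 1)
        w = comb(m, ks) * 0.5**m
        return ks, w
    draws = rng.binomial(m, 0.5, size=mc_samples)
    ks, counts = np.unique(draws, return_counts=True)
    return ks, counts / counts.sum()


def _expected_focal_payoff(x_focal: float, age_focal: int, resident: ResidentState,
                           env: EnvironmentParams,
                           rng: np.random.Generator | None = None) -> float:
    """Expected payoff of a focal individual with trait ``x_focal`` in a
    group whose other ``n - 1`` members are residents with ages drawn from
    the even mix."""
    m = env.n - 1
    ks, w = _age_mix_weights(m, rng)
    e1_others = ks * resident.x_young + (m - ks) * resident.x_old
    e1 = e1_others + x_focal
    e0 = env.n - e1
    shared = benefit_task0(e0, env) * benefit_task1(e1, env) / env.n
    return float(np.dot(w, np.atleast_1d(shared))) - float(total_cost(x_focal, age_focal, env))


def invasion_fitness(x_mut: float, age: int, resident: ResidentState,
                     env: EnvironmentParams,
                     rng: np.random.Generator | None = None) -> float:
    """Expected payoff advantage of a rare mutant of the given age class
    over a same-age resident; identically zero at ``x_mut`` equal to the
    resident trait."""
    if not 0.0 <= x_mut <= 1.0:
        raise ValueError(f"mutant trait must lie in [0, 1], got {x_mut}")
    return (_expected_focal_payoff(x_mut, age, resident, env, rng)
            - _expected_focal_payoff(resident.trait(age), age, resident, env, rng))


def _fitness_of_age(age: int, resident: ResidentState, env: EnvironmentParams):
    return lambda x: invasion_fitness(x, age, resident, env)


def _derivative(f, x: float, h: float) -> float:
    """Central difference, falling back to one-sided at the [0, 1] edges."""
    if x - h < 0.0:
        warnings.warn("boundary resident: using one-sided forward difference")
        return (f(x + h) - f(x)) / h
    if x + h > 1.0:
        warnings.warn("boundary resident: using one-sided backward difference")
        return (f(x) - f(x - h)) / h
    return (f(x + h) - f(x - h)) / (2.0 * h)


def selection_gradient(resident: ResidentState, env: EnvironmentParams,
                       h: float = 1e-5) -> tuple[float, float]:
    """Per-age-class selection gradient: derivative of invasion fitness in
    the mutant trait evaluated at the resident trait."""
    g = []
    for age in (0, 1):
        f = _fitness_of_age(age, resident, env)
        g.append(_derivative(f, resident.trait(age), h))
    return g[0], g[1]


def _second_derivative(f, x: float, h: float) -> float:
    lo, hi = max(0.0, x - h), min(1.0, x + h)
    xm = 0.5 * (lo + hi)   # re-centre if clipped
    step = 0.5 * (hi - lo)
    return (f(xm + step) - 2.0 * f(xm) + f(xm - step)) / step**2


def _conditional_gradient(age: int, x: float, resident: ResidentState,
                          env: EnvironmentParams, h: float) -> float:
    """Selection gradient of one age class when that class's resident trait
    is ``x`` (the other class held fixed)."""
    if age == 0:
        res = ResidentState(x_young=x, x_old=resident.x_old)
    else:
        res = ResidentState(x_young=resident.x_young, x_old=x)
    return selection_gradient(res, env, h)[age]


def classify_singular_point(resident: ResidentState, env: EnvironmentParams,
                            h: float = 1e-4) -> dict:
    """Second-order classification of a singular strategy, per age class.

    Evolutionary stability requires the invasion-fitness curvature in the
    mutant trait to be negative; convergence stability requires the
    conditional selection gradient to decrease through zero as the resident
    trait increases.  Convergence-stable but evolutionarily unstable points
    are *branching points*; points that are not convergence stable are
    repellers.
    """
    out: dict = {"x_young": resident.x_young, "x_old": resident.x_old}
    for age, label in ((0, "young"), (1, "old")):
        f = _fitness_of_age(age, resident, env)
        x = resident.trait(age)
        d2 = _second_derivative(f, x, h)
        gslope = _derivative(lambda xx: _conditional_gradient(age, xx, resident, env, h),
                             x, h)
        evol_stable = d2 < 0.0
        conv_stable = gslope < 0.0
        if conv_stable and evol_stable:
            label_cls = "ess"
        elif conv_stable:
            label_cls = "branching"
        else:
            label_cls = "repeller"
        out[f"class_{label}"] = label_cls
        out[f"curvature_{label}"] = d2
        out[f"gradient_slope_{label}"] = gslope
    classes = {out["class_young"], out["class_old"]}
    out["classification"] = ("branching" if "branching" in classes
                             else "ess" if classes == {"ess"} else "repeller")
    return out


def find_singular_strategies(env: EnvironmentParams, resolution: float = 0.05,
                             h: float = 1e-5, tol: float = 1e-8) -> list[dict]:
    """Locate and classify interior singular strategies.

    Seeds a damped Newton / fixed-point refinement from every coarse-grid
    cell of the ``(x_young, x_old)`` square where both gradient components
    change sign, then deduplicates converged roots and classifies each by
    :func:`classify_singular_point`.  An empty list is a legal outcome
    (e.g. boundary-attracted regimes).
    """
    from scipy.optimize import root

    grid = np.arange(_EPS_BOUNDARY, 1.0 - _EPS_BOUNDARY + 1e-12, resolution)

    def gradient_vec(v):
        xy = float(np.clip(v[0], 0.0, 1.0))
        xo = float(np.clip(v[1], 0.0, 1.0))
        return np.array(selection_gradient(ResidentState(xy, xo), env, h))

    g_grid = np.empty((grid.size, grid.size, 2))
    for i, xy in enumerate(grid):
        for j, xo in enumerate(grid):
            g_grid[i, j] = gradient_vec((xy, xo))

    seeds = []
    for i, j in product(range(grid.size - 1), repeat=2):
        block = g_grid[i:i + 2, j:j + 2]          # 2 x 2 x 2 corner values
        if (block[..., 0].min() < 0 < block[..., 0].max()
                and block[..., 1].min() < 0 < block[..., 1].max()):
            seeds.append((grid[i] + resolution / 2, grid[j] + resolution / 2))

    found: list[dict] = []
    for seed in seeds:
        sol = root(gradient_vec, np.array(seed), method="hybr", tol=tol)
        if not sol.success:
            continue
        xy, xo = (float(np.clip(v, 0.0, 1.0)) for v in sol.x)
        if not (_EPS_BOUNDARY <= xy <= 1 - _EPS_BOUNDARY
                and _EPS_BOUNDARY <= xo <= 1 - _EPS_BOUNDARY):
            continue
        if np.max(np.abs(gradient_vec((xy, xo)))) > 1e-6:
            continue
        if any(abs(r["x_young"] - xy) < 1e-3 and abs(r["x_old"] - xo) < 1e-3
               for r in found):
            continue
        entry = classify_singular_point(ResidentState(xy, xo), env, h=1e-4)
        entry["gradient_norm"] = float(np.linalg.norm(gradient_vec((xy, xo))))
        found.append(entry)
    return sorted(found, key=lambda r: (r["x_young"], r["x_old"]))


def boundary_analysis(env: EnvironmentParams, h: float = 1e-5) -> dict:
    """Sign of the selection gradient just inside each trait boundary, per
    age class, for symmetric residents pinned at that boundary.  A positive
    gradient at the upper edge (or negative at the lower edge) marks the
    boundary as attracting — the analytical picture of regulation failure."""
    out = {}
    for edge, x in (("lower", _EPS_BOUNDARY), ("upper", 1.0 - _EPS_BOUNDARY)):
        res = ResidentState(x, x)
        gy, go = selection_gradient(res, env, h)
        attracting = (gy > 0 and go > 0) if edge == "upper" else (gy < 0 and go < 0)
        out[edge] = {"gradient_young": gy, "gradient_old": go, "attracting": attracting}
    return out
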