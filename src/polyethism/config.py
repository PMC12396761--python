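"""Run configuration: validated parameter blocks, YAML round-trip, defaults.

A :class:`RunConfig` gathers four blocks — environment, learning, stimulus
and run — plus the master seed.  Every run embeds its fully resolved
configuration in its outputs.  Unknown keys are rejected with field-level
messages so that typos cannot silently fall back to defaults.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .payoffs import EnvironmentParams, benefit_task0, benefit_task1

__all__ = [
    "LearningParams",
    "StimulusParams",
    "RunParams",
    "RunConfig",
    "load_config",
    "save_config",
    "resolve_stimulus_params",
]


@dataclass(frozen=True)
class LearningParams:
    """Imitation-kernel and mutation settings.

    ``omega`` scales the age-similarity kernel, ``alpha`` in [0, 1] controls
    how strongly recruitment from the other age group is restricted
    (``alpha = 0``: similarity is ignored; larger ``alpha``: cross-age
    imitation is suppressed), ``mu`` is the per-individual mutation
    probability and ``sigma`` the Gaussian mutation step width.
    """

    omega: float = 10.0
    alpha: float = 0.5
    mu: float = 0.01
    sigma: float = 0.05

    def __post_init__(self):
        if self.omega < 0:
            raise ValueError(f"learning.omega must be >= 0, got {self.omega}")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"learning.alpha must lie in [0, 1], got {self.alpha}")
        if not 0.0 <= self.mu <= 1.0:
            raise ValueError(f"learning.mu must lie in [0, 1], got {self.mu}")
        if self.sigma <= 0:
            raise ValueError(f"learning.sigma must be > 0, got {self.sigma}")


@dataclass(frozen=True)
class StimulusParams:
    """Stimulus-coupling parameters of the SRT-SL model.

    ``gamma`` is the slope of the threshold sigmoid.  ``lambda1``/``phi1``
    are the gains turning aggregate benefit deficits into stimulus
    increments, ``lambda2``/``phi2`` the decays.  ``B0min`` is the minimum
    aggregate foraging benefit the colony must secure, ``B1max`` the maximum
    aggregate homeostatic benefit.

    Demand levels left as ``None`` are resolved at run time: ``B0min`` by
    the half-workforce rule ``K * B0(n/2)`` evaluated at the *calibration
    abundance* ``reference_b`` (a colony's foraging demand is a fixed
    requirement; it does not shrink because the environment turned scarce
    — this is exactly what makes low ``b`` stressful), and
    ``B1max = K * B1(n/2)``, the largest homeostatic benefit ``K`` groups
    can produce.  Gains left as ``None`` default to ``lambda2 / B0min`` and
    ``phi2 / B1max``, which makes each stimulus an exponential smoother of
    the *fractional* unmet demand of its task (time constant
    ``1/decay`` steps): the update is then a convex combination of the old
    level and the deficit fraction, so stimuli are confined to [0, 1] by
    construction.  Stimuli start at ``(S0_0, S1_0)`` and are additionally
    hard-clipped to [0, 1] after every update as a safety net for custom
    gains.
    """

    gamma: float = 10.0
    lambda1: float | None = None
    lambda2: float = 0.1
    phi1: float | None = None
    phi2: float = 0.1
    B0min: float | None = None
    B1max: float | None = None
    reference_b: float = 20.0
    S0_0: float = 0.5
    S1_0: float = 0.5

    def __post_init__(self):
        if self.gamma <= 0:
            raise ValueError(f"stimulus.gamma must be > 0, got {self.gamma}")
        for name in ("lambda1", "phi1", "B0min", "B1max"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"stimulus.{name} must be > 0 (or null), got {v}")
        if self.reference_b <= 0:
            raise ValueError(f"stimulus.reference_b must be > 0, got {self.reference_b}")
        for name in ("lambda2", "phi2"):
            if getattr(self, name) < 0:
                raise ValueError(f"stimulus.{name} must be >= 0, got {getattr(self, name)}")
        for name in ("S0_0", "S1_0"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"stimulus.{name} must lie in [0, 1], got {getattr(self, name)}")


@dataclass(frozen=True)
class RunParams:
    """Run geometry: population size ``N`` (split evenly into young and
    old), run length ``T`` in generations, which engine to use, the game
    (re)partition schedule, the analysis tail window, and the common initial
    trait ``x0`` (or uniform-random initialisation)."""

    N: int = 100
    T: int = 2000
    model: str = "srt"
    repartition: str | None = None   # None -> engine default
    tail_fraction: float = 0.2
    x0: float = 0.5
    init: str = "constant"           # "constant" | "uniform"

    def __post_init__(self):
        if int(self.N) != self.N or self.N < 2:
            raise ValueError(f"run.N must be an integer >= 2, got {self.N}")
        object.__setattr__(self, "N", int(self.N))
        if self.N % 2 != 0:
            raise ValueError(f"run.N must be even (equal young/old split), got {self.N}")
        if int(self.T) != self.T or self.T < 0:
            raise ValueError(f"run.T must be a non-negative integer, got {self.T}")
        object.__setattr__(self, "T", int(self.T))
        if self.model not in ("sl", "srt"):
            raise ValueError(f"run.model must be 'sl' or 'srt', got {self.model!r}")
        if self.repartition not in (None, "every_step", "fixed"):
            raise ValueError(
                f"run.repartition must be 'every_step', 'fixed' or null, got {self.repartition!r}"
            )
        if not 0.0 < self.tail_fraction <= 1.0:
            raise ValueError(f"run.tail_fraction must lie in (0, 1], got {self.tail_fraction}")
        if not 0.0 <= self.x0 <= 1.0:
            raise ValueError(f"run.x0 must lie in [0, 1], got {self.x0}")
        if self.init not in ("constant", "uniform"):
            raise ValueError(f"run.init must be 'constant' or 'uniform', got {self.init!r}")


_BLOCKS = {
    "environment": EnvironmentParams,
    "learning": LearningParams,
    "stimulus": StimulusParams,
    "run": RunParams,
}


@dataclass(frozen=True)
class RunConfig:
    environment: EnvironmentParams = field(default_factory=EnvironmentParams)
    learning: LearningParams = field(default_factory=LearningParams)
    stimulus: StimulusParams = field(default_factory=StimulusParams)
    run: RunParams = field(default_factory=RunParams)
    seed: int = 0

    def __post_init__(self):
        if int(self.seed) != self.seed:
            raise ValueError(f"seed must be an integer, got {self.seed!r}")
        object.__setattr__(self, "seed", int(self.seed))
        if self.run.N % self.environment.n != 0:
            raise ValueError(
                f"environment.n={self.environment.n} must divide run.N={self.run.N}"
            )

    # -- construction -------------------------------------------------------

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        if not isinstance(data, dict):
            raise ValueError("configuration must be a mapping")
        unknown = set(data) - set(_BLOCKS) - {"seed"}
        if unknown:
            raise ValueError(
                f"unknown configuration keys: {sorted(unknown)}; "
                f"allowed: {sorted(_BLOCKS) + ['seed']}"
            )
        kwargs: dict = {}
        for name, klass in _BLOCKS.items():
            block = data.get(name, {})
            if block is None:
                block = {}
            if not isinstance(block, dict):
                raise ValueError(f"configuration block {name!r} must be a mapping")
            allowed = {f.name for f in fields(klass)}
            bad = set(block) - allowed
            if bad:
                raise ValueError(
                    f"unknown keys in block {name!r}: {sorted(bad)}; allowed: {sorted(allowed)}"
                )
            kwargs[name] = klass(**block)
        kwargs["seed"] = data.get("seed", 0)
        return cls(**kwargs)

    def to_dict(self) -> dict:
        out: dict = {}
        for name in _BLOCKS:
            out[name] = dataclasses.asdict(getattr(self, name))
        out["seed"] = self.seed
        return out

    def replace(self, **blocks) -> "RunConfig":
        """Return a copy with whole blocks or the seed replaced, e.g.
        ``cfg.replace(environment=env, seed=7)``."""
        return dataclasses.replace(self, **blocks)

    def replace_fields(self, block: str, **kw) -> "RunConfig":
        """Return a copy with individual fields of one block replaced, e.g.
        ``cfg.replace_fields("environment", b=2.0, beta=0.45)``."""
        new_block = dataclasses.replace(getattr(self, block), **kw)
        return dataclasses.replace(self, **{block: new_block})


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration; defaults fill any field
    not present in the file."""
    with open(path, "r") as fh:
        data = yaml.safe_load(fh)
    if data is None:
        data = {}
    return RunConfig.from_dict(data)


def save_config(cfg: RunConfig, path) -> None:
    """Write the fully resolved configuration as YAML (round-trips through
    :func:`load_config`)."""
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))


def resolve_stimulus_params(sp: StimulusParams, env: EnvironmentParams, K: int) -> StimulusParams:
    """Fill the derived stimulus fields for a colony of ``K`` groups.

    ``B0min`` follows the half-workforce rule — the foraging benefit the
    colony needs half of every group to produce — evaluated at the
    calibration abundance ``reference_b`` (the demand is a property of the
    colony, not of the current environment, so scarcity leaves a real
    deficit).  ``B1max`` is the largest homeostatic benefit ``K`` groups
    can produce.  Default gains make each stimulus relax toward the
    fractional deficit of its task with time constant ``1/decay``.
    """
    if sp.B0min is not None:
        b0min = sp.B0min
    else:
        env_ref = dataclasses.replace(env, b=sp.reference_b)
        b0min = K * float(benefit_task0(env.n / 2.0, env_ref))
    b1max = sp.B1max if sp.B1max is not None else K * float(benefit_task1(env.n / 2.0, env))
    lam1 = sp.lambda1 if sp.lambda1 is not None else sp.lambda2 / b0min
    phi1 = sp.phi1 if sp.phi1 is not None else sp.phi2 / b1max
    return dataclasses.replace(sp, B0min=b0min, B1max=b1max, lambda1=lam1, phi1=phi1)
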