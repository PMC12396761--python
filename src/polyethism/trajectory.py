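"""Time-indexed record of a simulation run.

A :class:`Trajectory` stores the full per-generation state of either engine:
traits, ages, realised payoffs and — for the stimulus-coupled model — action
probabilities and stimulus levels.  It is the unit that the whole analysis
layer consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Trajectory"]


@dataclass
class Trajectory:
    """Recorded run of the SL or SRT-SL engine.

    Arrays are indexed by generation: ``x`` (and ``p``, ``stimuli`` for the
    stimulus-coupled model) have ``T + 1`` rows — the initial condition at
    row 0 followed by the ``T`` updated generations.  ``payoffs`` has ``T``
    rows; row ``t`` holds the payoffs earned from the state of generation
    ``t`` (the payoffs that drove the update to generation ``t + 1``).
    """

    model: str                       # "sl" or "srt"
    x: np.ndarray                    # (T+1, N) traits
    ages: np.ndarray                 # (N,) age classes, 0 young / 1 old
    payoffs: np.ndarray              # (T, N)
    p: np.ndarray | None = None      # (T+1, N) action probabilities (srt)
    stimuli: np.ndarray | None = None  # (T+1, 2) columns (S0, S1) (srt)
    config: dict = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.ages = np.asarray(self.ages, dtype=np.int8)
        self.payoffs = np.asarray(self.payoffs, dtype=float)
        if self.x.ndim != 2:
            raise ValueError("trajectory x must be 2-D (steps, individuals)")
        if self.x.shape[1] != self.ages.shape[0]:
            raise ValueError("trait array and age vector disagree on N")
        if self.payoffs.shape[0] not in (max(self.n_steps, 0), 0):
            raise ValueError("payoff array must have one row per completed generation")
        if self.p is not None:
            self.p = np.asarray(self.p, dtype=float)
            if self.p.shape != self.x.shape:
                raise ValueError("action-probability array must match trait array shape")
        if self.stimuli is not None:
            self.stimuli = np.asarray(self.stimuli, dtype=float)
            if self.stimuli.shape != (self.x.shape[0], 2):
                raise ValueError("stimulus array must have shape (steps, 2)")

    @property
    def n_individuals(self) -> int:
        return self.x.shape[1]

    @property
    def n_steps(self) -> int:
        """Number of completed generations T (rows are T + 1)."""
        return self.x.shape[0] - 1

    @property
    def engagement(self) -> np.ndarray:
        """Per-step engagement toward Task 1: action probabilities for the
        stimulus-coupled model, traits for the pure social-learning model."""
        return self.p if self.p is not None else self.x

    def tail_slice(self, tail_fraction: float) -> slice:
        """Row slice selecting the trailing ``tail_fraction`` of recorded steps."""
        if not 0.0 < tail_fraction <= 1.0:
            raise ValueError("tail_fraction must lie in (0, 1]")
        rows = self.x.shape[0]
        start = rows - max(1, int(round(tail_fraction * rows)))
        return slice(start, rows)
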