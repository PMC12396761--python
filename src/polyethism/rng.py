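"""Seeding discipline.

One master seed fully determines every stochastic draw in a run.  Each
stochastic component (partitioning, imitation, mutation, annealing, ...)
pulls from its own named substream derived from the master seed, so that
adding diagnostics or reordering independent components cannot perturb the
draws of another component.  Replicate seeds for sweeps are derived from a
master seed by an integer counter through the same mechanism.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "derive_seed"]


def _name_key(name: str) -> int:
    return zlib.crc32(name.encode("utf-8"))


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the named substream of ``seed``."""
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, _name_key(name)]))


def derive_seed(seed: int, index: int) -> int:
    """Derive a child seed (< 2**31) for replicate ``index`` of ``seed``."""
    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, _name_key("replicate"), int(index)])
    return int(ss.generate_state(1)[0] % (2**31))
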