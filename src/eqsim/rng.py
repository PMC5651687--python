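"""Seeded random-number plumbing with draw accounting.

Every stochastic decision in a run (tie-breaks, block shuffles, remainder
assignment) flows through a :class:`CountingRNG` so that outcomes are
bitwise reproducible from a seed and the number of draws consumed by each
trial can be audited.
"""

from __future__ import annotations

import zlib
from typing import Sequence

import numpy as np


class CountingRNG:
    """Thin wrapper over :class:`numpy.random.Generator` that counts calls."""

    def __init__(self, generator: np.random.Generator):
        self._gen = generator
        self.draws = 0

    @classmethod
    def from_seed(cls, seed) -> "CountingRNG":
        return cls(np.random.default_rng(seed))

    def choice(self, options: Sequence):
        """Uniform choice of one element."""
        self.draws += 1
        return options[int(self._gen.integers(len(options)))]

    def choose_indices(self, n: int, k: int) -> list[int]:
        """k distinct indices drawn uniformly from range(n)."""
        self.draws += 1
        return [int(i) for i in self._gen.choice(n, size=k, replace=False)]

    def shuffle(self, items: list) -> None:
        """In-place uniform shuffle."""
        self.draws += 1
        self._gen.shuffle(items)


def stage_rng(master_seed: int, stage_index: int, stage_name: str) -> CountingRNG:
    """Deterministic per-stage generator.

    Keyed on the master seed, the stage's position and a hash of its name,
    so every stage owns an independent, reproducible stream.
    """
    name_key = zlib.adler32(stage_name.encode("utf-8"))
    seq = np.random.SeedSequence(entropy=(int(master_seed), stage_index, name_key))
    return CountingRNG(np.random.default_rng(seq))
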