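"""Seed handling: every stochastic operation takes an int seed or a Generator."""

from __future__ import annotations

import numpy as np

RngLike = int | np.integer | np.random.Generator


def as_rng(rng: RngLike) -> np.random.Generator:
    """Normalize an integer seed or Generator to a numpy Generator.

    An integer seed always produces a fresh, reproducible stream; passing a
    Generator lets callers thread one stream through several operations.
    """
    if isinstance(rng, np.random.Generator):
        return rng
    if rng < 0:
        raise ValueError("seed must be nonnegative")
    return np.random.default_rng(int(rng))
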