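"""Deterministic seeding with independent substreams.

One master seed drives every source of randomness in the package. Each
consumer (rule generation, initial-state sampling, per-mutation randomness)
draws from its own substream so that, e.g., changing the number of initial
states never perturbs the generated rules.
"""

from __future__ import annotations

import numpy as np

# fixed substream identifiers
STREAM_RULES = 0
STREAM_STATES = 1
STREAM_MUTATION = 2
STREAM_NETWORK = 3


def derive_seed(seed: int | None, *key: int) -> int | None:
    """A stable 31-bit child seed for (seed, key); None stays None."""
    if seed is None:
        return None
    ss = np.random.SeedSequence(int(seed), spawn_key=tuple(key))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def substream(seed: int | None, *key: int) -> np.random.Generator:
    """Return a Generator for the substream identified by ``key``.

    ``key`` is a tuple of small integers (stream id, then optional indices
    such as the rule-set number). The same (seed, key) always yields the
    same stream; distinct keys yield statistically independent streams.
    """
    if seed is None:
        return np.random.default_rng()
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=tuple(key)))
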