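"""Deterministic seeding helpers.

One user-facing integer seed is fanned out into named substreams, so adding
simulations to one stage never perturbs the draws of another.
"""

from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int | None, *labels: object) -> np.random.Generator:
    """Independent generator derived from ``seed`` and a label path."""
    if seed is None:
        return np.random.default_rng()
    key = tuple(zlib.crc32(str(label).encode("utf8")) for label in labels)
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=key))


def as_generator(rng: np.random.Generator | int | None) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)
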