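"""Seed plumbing.

Every stochastic operation in the package draws from a stream derived from a
single top-level integer seed plus a short string label (operation name,
replicate index, ...). Streams for distinct labels are statistically
independent, so fixtures are reproducible operation by operation.
"""

from __future__ import annotations

import zlib

import numpy as np

MAX_SEED = 2**31 - 1


def derive_rng(seed: int, *labels) -> np.random.Generator:
    """Return a Generator keyed by ``seed`` and a tuple of labels.

    Labels may be strings or integers; they are hashed with CRC-32 so the
    derived entropy stays below 2**32 per word.
    """
    words = [int(seed) & MAX_SEED]
    for label in labels:
        words.append(zlib.crc32(str(label).encode("utf-8")))
    return np.random.default_rng(np.random.SeedSequence(words))


def spawn_seed(seed: int, *labels) -> int:
    """Derive a small (< 2**31) integer sub-seed, for APIs that take seeds."""
    return int(derive_rng(seed, *labels).integers(0, MAX_SEED))
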