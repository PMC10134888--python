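"""Seed-splitting helpers.

All randomness in the package flows from a single integer seed through named
child streams, so that every stage (taxon sampling, genome construction, noise,
permutation replicates) is independently reproducible and replayable.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_seed_sequence", "child_rng"]


def _token_to_int(token: object) -> int:
    """Map a stream-name token to a stable 32-bit integer."""
    if isinstance(token, (int, np.integer)):
        return int(token) & 0xFFFFFFFF
    return zlib.crc32(str(token).encode("utf-8"))


def child_seed_sequence(seed: int, *tokens: object) -> np.random.SeedSequence:
    """SeedSequence for the named child stream ``tokens`` of ``seed``."""
    return np.random.SeedSequence(
        entropy=int(seed), spawn_key=tuple(_token_to_int(t) for t in tokens)
    )


def child_rng(seed: int, *tokens: object) -> np.random.Generator:
    """Generator for the named child stream ``tokens`` of ``seed``.

    Streams with different token paths are statistically independent; the same
    (seed, tokens) pair always yields an identical generator state.
    """
    return np.random.default_rng(child_seed_sequence(seed, *tokens))
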