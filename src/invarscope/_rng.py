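"""Deterministic sub-seed derivation.

Every stochastic stage derives its generator from the run's global seed plus a
stage-identifying token, so no two stages ever share a seed stream and reruns
are bit-reproducible.
"""

from __future__ import annotations

import zlib

import numpy as np


def _token_key(token: str | int) -> int:
    if isinstance(token, int):
        return token & 0xFFFFFFFF
    return zlib.crc32(token.encode("utf-8"))


def derive_rng(seed: int, *tokens: str | int) -> np.random.Generator:
    """A Generator keyed by ``seed`` and a sequence of stage/item tokens."""
    entropy = [int(seed) & 0xFFFFFFFF] + [_token_key(t) for t in tokens]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def derive_int_seed(seed: int, *tokens: str | int) -> int:
    """A scalar seed (< 2**31) for libraries that take an integer seed."""
    entropy = [int(seed) & 0xFFFFFFFF] + [_token_key(t) for t in tokens]
    return int(np.random.SeedSequence(entropy).generate_state(1)[0] % (2**31))
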