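"""Deterministic random-stream derivation.

A single user-facing seed is expanded into independent per-purpose
substreams by hashing a string label into a ``SeedSequence`` spawn key.
Adding a new consumer label never perturbs the draws of existing ones,
which keeps multi-module runs reproducible as the package grows.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "derive_seed"]

_MOD = 2**31  # derived integer seeds stay below 2**31


def derive_seed(seed: int, *labels: str | int) -> int:
    """Derive a stable integer seed < 2**31 from *seed* and a label path."""
    h = zlib.crc32(repr(int(seed)).encode())
    for lab in labels:
        h = zlib.crc32(repr(lab).encode(), h)
    return h % _MOD


def substream(seed: int, *labels: str | int) -> np.random.Generator:
    """Return a ``numpy.random.Generator`` for the (seed, labels) stream."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) % _MOD, derive_seed(seed, *labels)])
    )
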