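"""Deterministic fan-out of a single user seed into per-stage streams."""

from __future__ import annotations

import zlib

import numpy as np


def child_rng(seed: int, label: str) -> np.random.Generator:
    """Return a generator seeded from (seed, label), stable across runs."""
    return np.random.default_rng([int(seed), zlib.crc32(label.encode())])
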