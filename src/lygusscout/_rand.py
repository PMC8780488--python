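"""Seed management: one pipeline seed fans out to per-stage child streams."""

from __future__ import annotations

import zlib

import numpy as np


def child_seed(seed: int, label: str) -> int:
    """Derive a reproducible child seed (< 2**31) from a seed and a label."""
    ss = np.random.SeedSequence([int(seed), zlib.crc32(label.encode())])
    return int(ss.generate_state(1, np.uint32)[0] % (2**31))


def rng_for(seed: int, label: str) -> np.random.Generator:
    return np.random.default_rng(child_seed(seed, label))
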