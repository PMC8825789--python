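"""Seed-substream utilities.

All randomness in the package flows through named substreams derived from a
single master seed, so that adding a food group, profile or bootstrap
replicate never perturbs the draws used by any other one.
"""
from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, *keys) -> np.random.Generator:
    """Return a Generator for the substream named by ``keys`` under ``seed``.

    Keys may be strings or integers; strings are hashed with CRC-32 so the
    mapping is stable across processes and Python versions (unlike ``hash``).
    """
    entropy = [int(seed) & 0x7FFFFFFF]
    for k in keys:
        if isinstance(k, (int, np.integer)):
            entropy.append(int(k) & 0xFFFFFFFF)
        else:
            entropy.append(zlib.crc32(str(k).encode("utf-8")))
    return np.random.default_rng(np.random.SeedSequence(entropy))
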