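"""Deterministic per-stage random streams.

Every stage of the pipeline draws from its own ``numpy`` Generator seeded
from (master seed, stage name), so adding or reordering stages never
perturbs another stage's draws and a single master seed reproduces the
entire experiment bit-for-bit.
"""

from __future__ import annotations

import zlib

import numpy as np


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """A Generator keyed by the master seed and a stage label."""
    key = zlib.crc32(stage.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence((int(seed), key)))
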