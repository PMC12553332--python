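"""Seed-derivation helpers.

A single user-facing seed drives every stochastic stage through
stage-name-hashed substreams, so e.g. adding association-test permutations
never perturbs the simulation draws.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["stage_seed", "stage_rng"]


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic 31-bit child seed for a named stage."""
    ss = np.random.SeedSequence([int(seed), zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Generator seeded from ``seed`` and the stage name."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(stage.encode())])
    )
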