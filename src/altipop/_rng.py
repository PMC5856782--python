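"""Deterministic seeding helpers.

A single user-facing integer seed is split into independent per-stage
streams keyed by stable stage names, so enabling or disabling one stage
of the pipeline never perturbs the random draws of another.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["stage_rng", "stage_seed"]


def stage_seed(seed: int, stage: str) -> np.random.SeedSequence:
    """Derive a child SeedSequence for *stage* from a global integer seed."""
    key = zlib.crc32(stage.encode("utf-8"))
    return np.random.SeedSequence(entropy=int(seed), spawn_key=(key,))


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """A Generator seeded deterministically by (seed, stage name)."""
    return np.random.default_rng(stage_seed(seed, stage))
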