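"""Named child random streams.

A single master seed drives a whole pipeline run; each stage pulls an
independent stream identified by a stable text label, so adding or removing
a stage never perturbs the draws of the others (unlike positional
``SeedSequence.spawn``).
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_seed_sequence", "child_rng"]


def child_seed_sequence(master_seed: int, label: str) -> np.random.SeedSequence:
    """Deterministic per-label seed sequence derived from ``master_seed``."""
    if master_seed < 0:
        raise ValueError("master seed must be non-negative")
    return np.random.SeedSequence(
        entropy=int(master_seed) & 0x7FFFFFFF,
        spawn_key=(zlib.crc32(label.encode("utf8")),),
    )


def child_rng(master_seed: int, label: str) -> np.random.Generator:
    """Generator for the named child stream of ``master_seed``."""
    return np.random.default_rng(child_seed_sequence(master_seed, label))
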