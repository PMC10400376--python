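"""Seed-derivation helpers.

Every stochastic component of the package draws from a named substream of a
single user-facing integer seed, so that runs are reproducible end to end and
independent components do not share (or race for) a single bit stream.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "spawn_seed"]


def _tag_to_int(tag: str) -> int:
    return zlib.crc32(tag.encode("utf-8"))


def substream(seed: int, tag: str) -> np.random.Generator:
    """Return a Generator for the named substream of ``seed``.

    The same (seed, tag) pair always yields an identical stream; distinct
    tags yield statistically independent streams.
    """
    return np.random.default_rng(np.random.SeedSequence([int(seed), _tag_to_int(tag)]))


def spawn_seed(seed: int, tag: str) -> int:
    """Derive a child integer seed (< 2**31) from (seed, tag)."""
    return int(substream(seed, tag).integers(0, 2**31 - 1))
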