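"""Seed plumbing: every stage draws from a named substream of one root seed."""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "substream_seed"]


def substream_seed(root_seed: int, *names: str) -> int:
    """A stable 31-bit seed for the named substream of ``root_seed``.

    Substreams are independent for distinct name tuples, reproducible across
    runs and platforms (crc32 is byte-stable), and safe to hand to libraries
    that want a plain integer seed.
    """
    keys = [int(root_seed) & 0xFFFFFFFF] + [zlib.crc32(n.encode()) for n in names]
    ss = np.random.SeedSequence(keys)
    return int(ss.generate_state(1)[0] % (2**31))


def substream(root_seed: int, *names: str) -> np.random.Generator:
    """A Generator on the named substream."""
    return np.random.default_rng(substream_seed(root_seed, *names))
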