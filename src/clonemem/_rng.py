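"""Seeded random-stream plumbing.

All simulation randomness derives from one integer seed.  Each named
component gets an independent stream via counter-based spawn keys, so a
generator can be re-run for one data modality without consuming draws that
belong to another.
"""

from __future__ import annotations

import zlib

import numpy as np


def stream(seed: int, *names: str) -> np.random.Generator:
    """Return an independent ``Generator`` for ``seed`` and a component path.

    The same (seed, names) pair always yields a bitwise-identical stream;
    distinct name paths yield statistically independent streams.
    """
    key = tuple(zlib.crc32(n.encode()) for n in names)
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))
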