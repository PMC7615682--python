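"""Deterministic substream seeding.

All randomness in the package flows from a single root seed.  Each logical
stream (a city's weather noise, an ensemble member's perturbation, a
country's coefficient draws, ...) derives its own generator from the root
seed plus a tuple of string labels, so that regenerating one artifact never
disturbs another and partial re-runs are reproducible.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def _label_key(label: object) -> int:
    return zlib.crc32(str(label).encode("utf-8"))


def substream(seed: int, *labels: object) -> np.random.Generator:
    """Return a generator keyed by ``seed`` and a stable hash of ``labels``.

    The same (seed, labels) pair always yields an identical stream; any
    change to either yields an effectively independent one.
    """
    entropy = [int(seed) & 0x7FFFFFFF] + [_label_key(l) for l in labels]
    return np.random.default_rng(np.random.SeedSequence(entropy))
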