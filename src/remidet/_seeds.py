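"""Deterministic named-purpose seed fan-out.

A single top-level integer seed is expanded into independent child streams
keyed by purpose names (e.g. ``("subject", "S03", "background")``), so adding
a consumer never perturbs the streams of existing ones.
"""

from __future__ import annotations

import zlib

import numpy as np


def seed_sequence(seed: int, *names) -> np.random.SeedSequence:
    keys = [zlib.crc32(str(n).encode("utf-8")) for n in names]
    return np.random.SeedSequence([int(seed) & 0x7FFFFFFF, *keys])


def rng_for(seed: int, *names) -> np.random.Generator:
    return np.random.default_rng(seed_sequence(seed, *names))


def int_seed(seed: int, *names) -> int:
    """A 31-bit integer seed for libraries that take plain ints."""
    return int(seed_sequence(seed, *names).generate_state(1)[0] % (2**31))
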