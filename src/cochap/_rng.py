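"""Deterministic, named random streams.

Every stochastic routine in the package draws from a stream derived from
(master seed, stream name).  The derivation uses ``numpy.random.SeedSequence``
with the CRC32 of the name as an extra entropy word, so results are
reproducible across platforms and independent between streams.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["stream"]


def stream(seed: int, *names: str) -> np.random.Generator:
    """Return the named random stream for a master seed.

    Parameters
    ----------
    seed : int
        Non-negative master seed.
    *names : str
        One or more labels identifying the consumer (e.g. ``"yule"``,
        ``"umbrella"``).  Different labels give independent streams.
    """
    if seed < 0:
        raise ValueError("seed must be non-negative")
    words = [zlib.crc32(n.encode()) for n in names]
    return np.random.default_rng(np.random.SeedSequence([int(seed), *words]))
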