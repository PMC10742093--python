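"""Reproducible, purpose-labelled random-number streams.

Every stochastic ingredient of a run (initialisation, wandering turns, escape
redraws, rebirth sampling) draws from its own named substream so that, e.g.,
changing how many wander turns are drawn cannot perturb rebirth outcomes.
Streams are derived from ``(seed, stream_id)`` via numpy's ``SeedSequence``
spawn-key mechanism, which guarantees statistically independent substreams.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["RNGStream", "make_rng"]


class RNGStream:
    """A named, reproducible random stream.

    Two streams with equal ``(seed, stream_id)`` produce identical draw
    sequences; distinct ids yield independent substreams.
    """

    def __init__(self, seed: int, stream_id: str):
        if seed < 0:
            raise ValueError("seed must be non-negative")
        self.seed = int(seed)
        self.stream_id = str(stream_id)
        key = zlib.crc32(self.stream_id.encode("utf-8"))
        self.generator = np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(key,))
        )

    # thin delegation — the full Generator is available as .generator
    def uniform(self, low=0.0, high=1.0, size=None):
        return self.generator.uniform(low, high, size)

    def normal(self, loc=0.0, scale=1.0, size=None):
        return self.generator.normal(loc, scale, size)

    def integers(self, low, high=None, size=None):
        return self.generator.integers(low, high, size)

    def choice(self, a, size=None, p=None):
        return self.generator.choice(a, size=size, p=p)

    def __repr__(self) -> str:  # pragma: no cover
        return f"RNGStream(seed={self.seed}, stream_id={self.stream_id!r})"


def make_rng(seed: int, stream_id: str) -> RNGStream:
    """Return the reproducible stream labelled ``stream_id`` for this seed."""
    return RNGStream(seed, stream_id)
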