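"""Seed plumbing.

Every public simulation function accepts ``seed`` as an int, a
:class:`numpy.random.SeedSequence`, or an already-constructed
:class:`numpy.random.Generator`.  Experiments derive one child
``SeedSequence`` per replicate from a single root, so replicate *i* is
reproducible independently of how many replicates are run (the first
half of a doubled run is bit-identical to the shorter run).
"""

from __future__ import annotations

from typing import Union

from numpy.random import Generator, SeedSequence, default_rng

SeedLike = Union[int, SeedSequence, Generator]


def seed_sequence(seed: SeedLike) -> SeedSequence:
    """Coerce ``seed`` to a SeedSequence (Generators are not coercible)."""
    if isinstance(seed, SeedSequence):
        return seed
    if isinstance(seed, Generator):
        raise TypeError("cannot derive a SeedSequence from a live Generator")
    return SeedSequence(int(seed))


def generator(seed: SeedLike) -> Generator:
    """Coerce ``seed`` to a Generator; live Generators pass through."""
    if isinstance(seed, Generator):
        return seed
    return default_rng(seed_sequence(seed))
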