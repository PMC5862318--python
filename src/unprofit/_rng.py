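"""Named, reproducible random substreams derived from one run seed.

Every source of randomness in the package (cohort generation, inner/outer
fold assignment, neural-net initialization, the falsification outcome) pulls
from a named child of a single integer seed, so a run is reproducible from
that one number and stages cannot perturb each other's streams.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "child_seed"]


def _spawn_key(names: tuple[str, ...]) -> tuple[int, ...]:
    return tuple(zlib.crc32(name.encode("utf-8")) for name in names)


def substream(seed: int, *names: str) -> np.random.Generator:
    """Return a Generator for the substream identified by ``names``."""
    ss = np.random.SeedSequence(int(seed), spawn_key=_spawn_key(names))
    return np.random.default_rng(ss)


def child_seed(seed: int, *names: str) -> int:
    """A 31-bit integer seed for libraries that take plain int seeds."""
    ss = np.random.SeedSequence(int(seed), spawn_key=_spawn_key(names))
    return int(ss.generate_state(1)[0] % (2**31))
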