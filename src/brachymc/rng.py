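"""Reproducible random-number streams.

The replay contract is: same ``(name, seed)`` -> bit-identical number
sequence.  The default generator is MT19937 (Mersenne Twister), whose
2^19937 - 1 period comfortably covers any run size this package produces.
The compiled transport kernels keep their own Mersenne Twister state,
seeded per run from the same integer seed.
"""

from __future__ import annotations

import numpy as np

_GENERATORS = {
    "mt19937": np.random.MT19937,
    "pcg64": np.random.PCG64,
}


class RandomStream:
    """A named, seeded random stream with bit-exact replay.

    Parameters
    ----------
    seed
        Non-negative integer seed.
    name
        Bit-generator name; ``"mt19937"`` (default) or ``"pcg64"``.
    """

    def __init__(self, seed: int, name: str = "mt19937"):
        if name not in _GENERATORS:
            raise ValueError(f"unknown generator {name!r}; choose from {sorted(_GENERATORS)}")
        self.name = name
        self.seed = int(seed)
        self.generator = np.random.Generator(_GENERATORS[name](self.seed))

    def replay(self) -> "RandomStream":
        """A fresh stream with the same (name, seed), replaying the sequence."""
        return RandomStream(self.seed, self.name)

    def spawn_seed(self, stream_index: int) -> int:
        """Derive a child seed (< 2^31) for a compiled kernel or shard."""
        ss = np.random.SeedSequence([self.seed, int(stream_index)])
        return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31 - 1)) + 1

    # Convenience pass-throughs -------------------------------------------------
    def random(self, *args, **kwargs):
        return self.generator.random(*args, **kwargs)

    def uniform(self, *args, **kwargs):
        return self.generator.uniform(*args, **kwargs)

    def integers(self, *args, **kwargs):
        return self.generator.integers(*args, **kwargs)

    def __repr__(self) -> str:  # pragma: no cover
        return f"RandomStream(name={self.name!r}, seed={self.seed})"
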