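"""Small internal helpers: seeding and window arithmetic."""
from __future__ import annotations

import numpy as np

MAX_SEED = 2**31 - 1


def rng_from(seed) -> np.random.Generator:
    """Return a Generator; accepts an int seed, None, or an existing rng."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def child_seeds(seed: int, n: int) -> list[int]:
    """Derive ``n`` independent child seeds (< 2**31) from one parent seed."""
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0]) % MAX_SEED for c in ss.spawn(n)]
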