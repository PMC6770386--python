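"""Small shared numeric helpers."""

from __future__ import annotations

import math


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero.

    Used everywhere a read budget is derived from a ratio, so that
    "~6 reads/virus"-style budgets are reproducible regardless of the
    platform's default (banker's) rounding.
    """
    if x >= 0:
        return int(math.floor(x + 0.5))
    return -int(math.floor(-x + 0.5))


def derive_seed(base_seed: int, *key: int) -> int:
    """Derive an independent child seed (< 2**31) from a base seed.

    Deterministic in (base_seed, key); distinct keys give statistically
    independent streams via numpy's SeedSequence spawning.
    """
    import numpy as np

    ss = np.random.SeedSequence(entropy=base_seed, spawn_key=tuple(key))
    return int(ss.generate_state(1)[0] % (2**31))
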