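"""Deterministic seed derivation for the multi-run protocol.

A single master seed drives the whole workflow; every nested source of
randomness (run, fold pipeline, pruning level, permutation repeats, trial
model seeds) gets its own child seed derived from the master and a structural
key, so identical inputs always reproduce identical results.
"""

from __future__ import annotations

import numpy as np

_MOD = 2**31 - 1


def derive_seed(master: int, *key: int) -> int:
    """Derive a child seed (< 2^31) from a master seed and an integer key path."""
    ss = np.random.SeedSequence([int(master) & 0xFFFFFFFF, *[int(k) & 0xFFFFFFFF for k in key]])
    return int(ss.generate_state(1)[0] % _MOD)
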