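"""Stable child-seed derivation.

One global seed governs a run; every stage (and every gene set's permutation
null) derives its own generator by hashing (seed, stage name...). This keeps
stages reproducible in isolation and lets paired analyses (tumor vs healthy
enrichment of the same set) share identical permutation draws.
"""

from __future__ import annotations

import hashlib

import numpy as np


def child_seed(seed: int, *names: str) -> int:
    key = "|".join([str(int(seed)), *names]).encode()
    digest = hashlib.sha256(key).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def child_rng(seed: int, *names: str) -> np.random.Generator:
    return np.random.default_rng(child_seed(seed, *names))
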