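"""Seed policy: one global seed, deterministic child streams per operation.

Every stochastic operation draws its generator from ``child_rng(seed, name, index)``
so that a whole pipeline is reproducible from a single integer and independent
operations never share a stream.
"""
from __future__ import annotations

import hashlib

import numpy as np


def _stable_hash(name: str) -> int:
    """Platform-independent 32-bit hash of an operation name."""
    digest = hashlib.blake2s(name.encode("utf-8"), digest_size=4).digest()
    return int.from_bytes(digest, "little")


def child_seed_sequence(seed: int, name: str, index: int = 0) -> np.random.SeedSequence:
    return np.random.SeedSequence([int(seed), _stable_hash(name), int(index)])


def child_rng(seed: int, name: str, index: int = 0) -> np.random.Generator:
    """Generator for operation `name`, replicate `index`, under global `seed`."""
    return np.random.default_rng(child_seed_sequence(seed, name, index))
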