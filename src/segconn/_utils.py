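"""Shared helpers: seeding, validation."""

from __future__ import annotations

import numpy as np


def spawn_rngs(seed, n):
    """Derive ``n`` independent child generators from one master seed.

    Children are produced with :class:`numpy.random.SeedSequence` spawning, so
    every stage of a run gets its own stream and adding a consumer never
    perturbs the draws of another.
    """
    ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(child) for child in ss.spawn(n)]


def as_rng(seed_or_rng):
    """Accept an int seed, a Generator, or None and return a Generator."""
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def check_probability_vector(p, atol=1e-9):
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("distribution must be a non-empty 1-d vector")
    if np.any(p < 0):
        raise ValueError("distribution entries must be non-negative")
    if abs(p.sum() - 1.0) > atol:
        raise ValueError(f"distribution must sum to 1 (got {p.sum():.12f})")
    return p


def check_symmetric_adjacency(adj):
    adj = np.asarray(adj, dtype=bool)
    if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.array_equal(adj, adj.T):
        raise ValueError("adjacency must be symmetric")
    if np.any(np.diag(adj)):
        raise ValueError("adjacency diagonal must be zero")
    return adj
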