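"""Photon-to-pixel label-vector combinatorics.

A *label vector* ``v = (v_1, ..., v_L)`` assigns each detected photon, in
chronological order, to the pixel that captured it.  For per-pixel counts
``z = (z_1, ..., z_K)`` with ``L = sum z_k``, the consistent label vectors
form the set ``A(z)`` of distinct permutations of the multiset
``{k repeated z_k times}``; its cardinality is the multinomial coefficient
``L! / (z_1! ... z_K!)``.  The pixelated-detector likelihood sums one term
per label vector, so the cardinality is guarded by a hard cap to turn the
combinatorial blow-up at large photon counts into a typed error.

Labels are 1-based.
"""

from __future__ import annotations

import math
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "count_label_vectors",
    "enumerate_label_vectors",
    "sample_label_vectors",
    "counts_from_labels",
    "TooManyConfigurationsError",
]

DEFAULT_CAP = 10 ** 6


class TooManyConfigurationsError(ValueError):
    """The label-vector set is too large to enumerate exactly."""

    def __init__(self, count: int, cap: int):
        self.count = count
        self.cap = cap
        super().__init__(
            f"label-vector set has {count} elements, above the cap {cap}; "
            "exact enumeration refused")


def _validate_counts(z: Sequence[int]) -> list[int]:
    out = [int(v) for v in z]
    if any(v < 0 for v in out) or any(v != float(w) for v, w in zip(out, z)):
        raise ValueError("counts must be non-negative integers")
    return out


def count_label_vectors(z: Sequence[int]) -> int:
    """Exact cardinality ``L! / (z_1! ... z_K!)`` (arbitrary precision)."""
    z = _validate_counts(z)
    L = sum(z)
    out = math.factorial(L)
    for v in z:
        out //= math.factorial(v)
    return out


def enumerate_label_vectors(z: Sequence[int], cap: int = DEFAULT_CAP
                            ) -> Iterator[tuple[int, ...]]:
    """Lazily yield every label vector consistent with counts ``z``.

    Each distinct permutation of the multiset ``{k x z_k}`` is produced
    exactly once, in lexicographic order, as a tuple of 1-based labels.
    Raises :class:`TooManyConfigurationsError` if the cardinality exceeds
    ``cap``.
    """
    z = _validate_counts(z)
    n = count_label_vectors(z)
    if n > cap:
        raise TooManyConfigurationsError(n, cap)

    def rec(remaining: list[int], prefix: list[int]) -> Iterator[tuple[int, ...]]:
        if sum(remaining) == 0:
            yield tuple(prefix)
            return
        for k, left in enumerate(remaining):
            if left:
                remaining[k] -= 1
                prefix.append(k + 1)
                yield from rec(remaining, prefix)
                prefix.pop()
                remaining[k] += 1

    return rec(list(z), [])


def sample_label_vectors(z: Sequence[int], n: int, rng: np.random.Generator
                         ) -> np.ndarray:
    """Uniform random label vectors consistent with ``z`` (approximate tool).

    Random shuffles of the multiset are uniform over its distinct
    permutations.  Intended for Monte Carlo estimation of the label sum when
    the exact enumeration is above the cap; the resulting likelihoods are
    approximate and this path is never used implicitly.
    """
    z = _validate_counts(z)
    base = np.repeat(np.arange(1, len(z) + 1), z)
    out = np.empty((n, len(base)), dtype=np.int64)
    for i in range(n):
        out[i] = rng.permutation(base)
    return out


def counts_from_labels(v: Sequence[int], K: int) -> np.ndarray:
    """Per-pixel counts ``z_k = #\\{l : v_l = k\\}`` from a label vector."""
    v = np.asarray(v, dtype=np.int64)
    if v.size and (v.min() < 1 or v.max() > K):
        raise ValueError("labels must lie in 1..K")
    return np.bincount(v - 1, minlength=K) if v.size else np.zeros(K, dtype=np.int64)
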