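"""Independent brute-force oracles used only by the test suite.

These deliberately share no code with the package implementation: the
inverted-repeat oracle enumerates every circular interval pair via the
full anti-diagonal match matrix, and the alignment oracle is a
top-down memoised recursion over the complete (i, j, state) space.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

_COMP = str.maketrans("ACGTN", "TGCAN")


def brute_force_inverted_repeat(seq: str, min_len: int, frac: float):
    """All-interval-pairs search for the longest inverted repeat on a
    circular sequence.

    Considers every pair of disjoint circular intervals X = [a, a+L),
    Y = [b, b+L), matching seq[a+t] against the complement of
    seq[b+L-1-t] (indices mod n), allowing at most floor(frac * L)
    mismatches.  Returns ``(L, pairs)`` where pairs is the set of
    (smaller start, larger start) tuples achieving the maximum, or
    None if no qualifying pair of length >= min_len exists.
    """
    n = len(seq)
    s = np.frombuffer(seq.encode(), dtype=np.uint8)
    comp = np.frombuffer(seq.translate(_COMP).encode(), dtype=np.uint8)
    idx = np.arange(n)
    best_len = 0
    best_pairs: set[tuple[int, int]] = set()
    A = idx[:, None]
    Ls = np.arange(1, n)[None, :]
    max_budget = np.floor(frac * Ls)
    for c in range(n):
        m = (s == comp[(c - idx) % n]) & (s != ord("N"))
        P = np.concatenate([[0], np.cumsum(np.concatenate([m, m]))])
        mism = Ls - (P[A + Ls] - P[A])
        yb = (c - A - Ls + 1) % n
        # X = [a, a+L) and Y = [yb, yb+L) are circularly disjoint iff
        # the two gaps between them sum to n - 2L
        d1 = (yb - (A + Ls)) % n
        d2 = (A - (yb + Ls)) % n
        valid = (Ls >= min_len) & (d1 + d2 == n - 2 * Ls) \
            & (mism <= max_budget)
        if not valid.any():
            continue
        lmax = int(Ls[0][valid.any(axis=0)].max())
        if lmax < best_len:
            continue
        rows, cols = np.nonzero(valid & (Ls == lmax))
        pairs = set()
        for a_, col in zip(rows, cols):
            b_ = int((c - a_ - lmax + 1) % n)
            pairs.add((min(int(a_), b_), max(int(a_), b_)))
        if lmax > best_len:
            best_len, best_pairs = lmax, pairs
        else:
            best_pairs |= pairs
    if best_len < min_len:
        return None
    return best_len, best_pairs


def affine_dp_score(ref: str, tgt: str, match: int = 2, mismatch: int = -3,
                    gap_open: int = -8, gap_extend: int = -2) -> int:
    """Exhaustive affine-gap global alignment score by memoised recursion.

    State: (i, j, g) where g is the gap state an immediately following
    gap column would extend (0 none, 1 gap-in-target, 2 gap-in-ref).
    """
    R, T = len(ref), len(tgt)
    NEG = float("-inf")

    @lru_cache(maxsize=None)
    def go(i: int, j: int, g: int) -> float:
        if i == R and j == T:
            return 0
        best = NEG
        if i < R and j < T:
            sub = match if ref[i] == tgt[j] else mismatch
            best = max(best, sub + go(i + 1, j + 1, 0))
        if i < R:
            cost = gap_extend + (0 if g == 1 else gap_open)
            best = max(best, cost + go(i + 1, j, 1))
        if j < T:
            cost = gap_extend + (0 if g == 2 else gap_open)
            best = max(best, cost + go(i, j + 1, 2))
        return best

    result = go(0, 0, 0)
    go.cache_clear()
    return int(result)
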