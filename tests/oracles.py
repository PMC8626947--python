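"""Independent brute-force oracles used by the test suite.

These deliberately reimplement the quantities under test with the most
transparent algorithm available (full dynamic programming with explicit
traceback, per-base counting, sliding-window Hamming scans, exhaustive
enumeration) and share no code with the package's optimized paths.
"""

from __future__ import annotations

import itertools
from fractions import Fraction
from math import comb

import numpy as np

MATCH, MISMATCH, GAP = 1, -1, -2


def fit_alignment_oracle(A: np.ndarray, B: np.ndarray):
    """Full-DP 'fit' alignment of query B inside target A.

    Free terminal gaps on the target only; returns
    (score, matches, columns, paired) of the optimal path, with the same
    deterministic tie-breaking (diagonal > up > left on ties, smallest
    end row) as the package aligner.
    """
    n, m = len(A), len(B)
    H = np.zeros((n + 1, m + 1), dtype=np.int64)
    TB = np.zeros((n + 1, m + 1), dtype=np.int8)
    H[0, :] = GAP * np.arange(m + 1)
    TB[0, 1:] = 2
    j2 = 2 * np.arange(0, m + 1, dtype=np.int64)
    for i in range(1, n + 1):
        s = np.where(B == A[i - 1], MATCH, MISMATCH).astype(np.int64)
        diag = H[i - 1, :-1] + s
        up = H[i - 1, 1:] + GAP
        cand = np.maximum(diag, up)
        tb = np.where(diag >= up, 0, 1).astype(np.int8)
        # left moves chain within the row (including from column 0, which
        # is the free-leading-target boundary 0): running decayed maximum
        H[i, 0] = 0
        g = np.concatenate(([H[i, 0]], cand)) + j2
        acc = np.maximum.accumulate(g)
        row = acc[1:] - j2[1:]
        left_used = acc[1:] > g[1:]
        tb[left_used] = 2
        H[i, 1:] = row
        TB[i, 1:] = tb
    bi = int(np.argmax(H[:, m]))  # smallest index on ties, as in the package
    score = int(H[bi, m])
    i, j = bi, m
    matches = columns = paired = 0
    while i > 0 and j > 0:
        t = TB[i, j]
        columns += 1
        if t == 0:
            matches += int(A[i - 1] == B[j - 1])
            paired += 1
            i, j = i - 1, j - 1
        elif t == 1:
            i -= 1
        else:
            j -= 1
    columns += j
    return score, matches, columns, paired


def coverage_oracle(intervals, length: int) -> np.ndarray:
    """Per-base depth by literally counting interval membership."""
    depth = np.zeros(length, dtype=int)
    for start, end in intervals:
        for pos in range(length):
            if start <= pos < end:
                depth[pos] += 1
    return depth


def trimmed_mean_oracle(depth: np.ndarray, trim: float) -> float:
    vals = sorted(depth.tolist())
    k = int(trim * len(vals))
    kept = vals[k: len(vals) - k] if k else vals
    return sum(kept) / len(kept)


def hamming_scan_oracle(spacer: str, target: str, max_mismatch: int):
    """Naive O(n*m) sliding scan; returns (position, mismatches) hits."""
    m = len(spacer)
    hits = []
    for pos in range(len(target) - m + 1):
        mm = sum(a != b for a, b in zip(spacer, target[pos: pos + m]))
        if mm <= max_mismatch:
            hits.append((pos, mm))
    return hits


def hypergeom_tail_enumeration(M: int, na: int, nb: int, c: int) -> Fraction:
    """P(|A & B| >= c) by enumerating every possible draw of B.

    A is fixed to the first ``na`` elements; all C(M, nb) subsets B are
    enumerated and counted exactly (rationals, no floating point).
    """
    A = set(range(na))
    hits = sum(
        1 for B in itertools.combinations(range(M), nb) if len(A & set(B)) >= c
    )
    return Fraction(hits, comb(M, nb))


def modularity_best_bipartition(adj: np.ndarray):
    """Exhaustive best-modularity bipartition of a small graph."""
    n = adj.shape[0]
    two_m = adj.sum()
    deg = adj.sum(axis=1)

    def modularity(labels):
        q = 0.0
        for i in range(n):
            for j in range(n):
                if labels[i] == labels[j]:
                    q += adj[i, j] - deg[i] * deg[j] / two_m
        return q / two_m

    best, best_q = None, -np.inf
    for bits in range(1, 2 ** (n - 1)):
        labels = [(bits >> i) & 1 for i in range(n)]
        q = modularity(labels)
        if q > best_q:
            best_q, best = q, labels
    groups = [frozenset(i for i in range(n) if best[i] == s) for s in (0, 1)]
    return {g for g in groups if g}
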