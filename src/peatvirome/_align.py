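"""Semi-global pairwise alignment with free terminal gaps.

This is the identity engine behind species-level (nucleotide) and
protein-cluster (amino-acid) greedy clustering.  Scoring is fixed at
match +1, mismatch -1, gap -2, terminal gaps free; identity -- not the
score -- is the decision quantity downstream.

Small problems (up to ~2 kb x 2 kb) are solved with the full dynamic
program.  Larger problems use a banded dynamic program whose band is
seeded from shared k-mer diagonals; the band is generous enough that,
for substitution-dominated sequence pairs, the banded result equals the
full result.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

MATCH = 1
MISMATCH = -1
GAP = -2

# full DP above this many cells would thrash memory; switch to banded
_FULL_DP_MAX_CELLS = 4_200_000
_BAND_PAD = 48
_SEED_K = 15

_COMPLEMENT = bytes.maketrans(b"ACGTRYSWKMBDHVN", b"TGCAYRSWMKVHDBN")


def encode(seq: str) -> np.ndarray:
    """Byte-encode an uppercase sequence for the aligner."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()


def revcomp(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class AlignmentStats:
    """Path statistics of the best-scoring semi-global alignment."""

    score: int
    matches: int
    columns: int
    paired: int  # residue-paired (non-gap) columns, i.e. aligned query bases

    @property
    def identity(self) -> float:
        return self.matches / self.columns if self.columns else 0.0


@njit(cache=True)
def _dp_full(A, B):  # pragma: no cover - exercised via align()
    # "fit" alignment: query B fully consumed, terminal gaps free on the
    # target A only.  H[i,0] = 0 (free leading target), H[0,j] = GAP*j
    # (query overhang is paid), best end anywhere in the last column.
    n = A.shape[0]
    m = B.shape[0]
    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    TB = np.zeros((n + 1, m + 1), dtype=np.int8)
    for j in range(1, m + 1):
        H[0, j] = GAP * j
        TB[0, j] = 2
    for i in range(1, n + 1):
        ai = A[i - 1]
        for j in range(1, m + 1):
            s = MATCH if B[j - 1] == ai else MISMATCH
            best = H[i - 1, j - 1] + s
            t = 0
            u = H[i - 1, j] + GAP
            if u > best:
                best = u
                t = 1
            l = H[i, j - 1] + GAP
            if l > best:
                best = l
                t = 2
            H[i, j] = best
            TB[i, j] = t
    bi, bs = 0, H[0, m]
    for i in range(1, n + 1):
        if H[i, m] > bs:
            bs = H[i, m]
            bi = i
    matches = 0
    columns = 0
    paired = 0
    i, j = bi, m
    while i > 0 and j > 0:
        t = TB[i, j]
        columns += 1
        if t == 0:
            if A[i - 1] == B[j - 1]:
                matches += 1
            paired += 1
            i -= 1
            j -= 1
        elif t == 1:
            i -= 1
        else:
            j -= 1
    columns += j  # leading query overhang beyond the target start
    return bs, matches, columns, paired


@njit(cache=True)
def _dp_banded(A, B, offmin, offmax):  # pragma: no cover - via align()
    # fit alignment restricted to diagonals j - i in [offmin, offmax];
    # cells outside the band are -inf.  Same recurrence and boundary
    # conditions as _dp_full.
    n = A.shape[0]
    m = B.shape[0]
    w = offmax - offmin + 1
    NEG = np.int32(-(10**9))
    H = np.full((n + 1, w), NEG, dtype=np.int32)
    TB = np.zeros((n + 1, w), dtype=np.int8)
    for k in range(w):
        j = offmin + k
        if 0 <= j <= m:
            H[0, k] = GAP * j
            TB[0, k] = 2
    bs = NEG
    bi = -1
    for i in range(1, n + 1):
        ai = A[i - 1]
        lo = i + offmin
        hi = i + offmax
        if lo < 0:
            lo = 0
        if hi > m:
            hi = m
        for j in range(lo, hi + 1):
            k = j - i - offmin
            if j == 0:
                H[i, k] = 0  # free leading target gap
                TB[i, k] = 1
                continue
            s = MATCH if B[j - 1] == ai else MISMATCH
            best = NEG
            t = 0
            d = H[i - 1, k]  # diagonal (i-1, j-1)
            if d > NEG:
                best = d + s
            if k + 1 < w:
                u = H[i - 1, k + 1]  # up (i-1, j)
                if u > NEG and u + GAP > best:
                    best = u + GAP
                    t = 1
            if k - 1 >= 0:
                l = H[i, k - 1]  # left (i, j-1)
                if l > NEG and l + GAP > best:
                    best = l + GAP
                    t = 2
            if best <= NEG:
                continue
            H[i, k] = best
            TB[i, k] = t
            if j == m and best > bs:
                bs = best
                bi = i
    if bi < 0:
        return np.int32(0), 0, 0, 0
    matches = 0
    columns = 0
    paired = 0
    i = bi
    j = m
    while i > 0 and j > 0:
        k = j - i - offmin
        t = TB[i, k]
        columns += 1
        if t == 0:
            if A[i - 1] == B[j - 1]:
                matches += 1
            paired += 1
            i -= 1
            j -= 1
        elif t == 1:
            i -= 1
        else:
            j -= 1
    columns += j
    return bs, matches, columns, paired


def _kmer_offsets(A: np.ndarray, B: np.ndarray, k: int = _SEED_K) -> np.ndarray:
    """Diagonal offsets (j - i) of exact shared k-mers, by hashing."""
    if len(A) < k or len(B) < k:
        return np.empty(0, dtype=np.int64)
    index: dict[bytes, list[int]] = {}
    bb = B.tobytes()
    for j in range(len(B) - k + 1):
        index.setdefault(bb[j : j + k], []).append(j)
    ab = A.tobytes()
    offs = []
    for i in range(len(A) - k + 1):
        hits = index.get(ab[i : i + k])
        if hits:
            for j in hits:
                offs.append(j - i)
    return np.asarray(offs, dtype=np.int64)


def align(A: np.ndarray, B: np.ndarray) -> AlignmentStats:
    """Best semi-global alignment of query ``B`` against target ``A``.

    Exact full dynamic programming for small problems; k-mer-seeded
    banded dynamic programming for large ones.
    """
    n, m = len(A), len(B)
    if n == 0 or m == 0:
        return AlignmentStats(0, 0, 0, 0)
    if n * m <= _FULL_DP_MAX_CELLS:
        return AlignmentStats(*_dp_full(A, B))
    offs = _kmer_offsets(A, B)
    if offs.size == 0:
        # no seed: fall back to a main-diagonal band wide enough for the
        # length difference; unrelated long pairs land here and score low
        offmin, offmax = -_BAND_PAD * 4, (m - n) + _BAND_PAD * 4
    else:
        offmin = int(offs.min()) - _BAND_PAD
        offmax = int(offs.max()) + _BAND_PAD
    if offmin > offmax:
        offmin, offmax = offmax, offmin
    return AlignmentStats(*_dp_banded(A, B, offmin, offmax))


_NT_LUT = np.zeros(256, dtype=np.int64)
for _i, _c in enumerate(b"ACGT"):
    _NT_LUT[_c] = _i


def kmer_codes(enc: np.ndarray, k: int = _SEED_K, alphabet: str = "nucleotide") -> np.ndarray:
    """Sorted unique integer codes of all k-mers of a byte-encoded sequence.

    Nucleotides are packed 2 bits per base (k up to 31); other alphabets
    use the raw byte (k up to 7).  Used as a cheap prefilter signature
    for greedy clustering.
    """
    if len(enc) < k:
        return np.empty(0, dtype=np.int64)
    if alphabet == "nucleotide":
        codes, base = _NT_LUT[enc], 4
    else:
        codes, base = enc.astype(np.int64), 256
    win = np.lib.stride_tricks.sliding_window_view(codes, k)
    powers = base ** np.arange(k, dtype=np.int64)
    return np.unique(win @ powers)


def code_overlap(sa: np.ndarray, sb: np.ndarray) -> float:
    """Shared fraction of the smaller k-mer code set."""
    if sa.size == 0 or sb.size == 0:
        return 0.0
    inter = np.intersect1d(sa, sb, assume_unique=True).size
    return inter / min(sa.size, sb.size)


def shared_kmer_fraction(
    A: np.ndarray, B: np.ndarray, k: int = _SEED_K, alphabet: str = "nucleotide"
) -> float:
    """Fraction of the smaller sequence's k-mer set shared with the other.

    Pairs above the species or protein-cluster identity threshold share a
    large fraction of exact k-mers, unrelated pairs essentially none.
    """
    return code_overlap(kmer_codes(A, k, alphabet), kmer_codes(B, k, alphabet))
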