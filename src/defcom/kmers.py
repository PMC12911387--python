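"""Integer k-mer encoding and sorted-array membership utilities.

Sequences are held as uint8 code arrays (A=0, C=1, G=2, T=3) and k-mers as
uint64 packed 2-bit codes, so k <= 31. Membership queries run as vectorized
binary searches against sorted unique k-mer arrays.
"""

from __future__ import annotations

import numpy as np

_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i
    _ENCODE[_b + 32] = _i  # lowercase

_DECODE = np.frombuffer(b"ACGT", dtype=np.uint8)


def encode_sequence(seq: str) -> np.ndarray:
    """Encode an ACGT string to a uint8 code array; rejects other symbols."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _ENCODE[raw]
    if codes.max(initial=0) > 3:
        bad = chr(raw[codes > 3][0])
        raise ValueError(f"sequence contains non-ACGT symbol {bad!r}")
    return codes


def decode_sequence(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode("ascii")


def kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """All overlapping k-mers of a code array as uint64, in sequence order."""
    if not 1 <= k <= 31:
        raise ValueError("k must be in [1, 31]")
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    vals = codes.astype(np.uint64)
    out = np.zeros(n, dtype=np.uint64)
    for i in range(k):
        out <<= np.uint64(2)
        out |= vals[i : i + n]
    return out


def kmer_codes_2d(reads: np.ndarray, k: int) -> np.ndarray:
    """k-mers for a (n_reads, read_len) code matrix -> (n_reads, L-k+1) uint64."""
    n, L = reads.shape
    m = L - k + 1
    if m <= 0:
        raise ValueError(f"reads of length {L} are shorter than k={k}")
    vals = reads.astype(np.uint64)
    out = np.zeros((n, m), dtype=np.uint64)
    for i in range(k):
        out <<= np.uint64(2)
        out |= vals[:, i : i + m]
    return out


def kmer_index(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Sorted unique k-mers of a sequence plus the leftmost position of each."""
    km = kmer_codes(codes, k)
    uniq, first = np.unique(km, return_index=True)
    return uniq, first.astype(np.int64)


def member_mask(query: np.ndarray, sorted_ref: np.ndarray) -> np.ndarray:
    """Boolean mask: which query k-mers occur in the sorted reference array."""
    if sorted_ref.size == 0:
        return np.zeros(query.shape, dtype=bool)
    idx = np.searchsorted(sorted_ref, query)
    idx[idx == sorted_ref.size] = sorted_ref.size - 1
    return sorted_ref[idx] == query


def lookup_positions(query: np.ndarray, sorted_ref: np.ndarray, positions: np.ndarray) -> np.ndarray:
    """Leftmost reference position of each query k-mer (must all be members)."""
    idx = np.searchsorted(sorted_ref, query)
    return positions[idx]
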