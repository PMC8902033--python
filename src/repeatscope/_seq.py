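"""Low-level sequence utilities shared across the package.

Sequences cross module boundaries as plain uppercase ACGT strings; internally
they are handled as uint8 byte arrays so that alignment and k-mer operations
vectorize. Only substitution differences ever occur in this package's world,
so arrays of equal length compare column-wise everywhere.
"""

from __future__ import annotations

import numpy as np

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

_COMP = np.zeros(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTNacgtn", b"TGCANtgcan"):
    _COMP[_a] = _b

# 2-bit codes for k-mer packing; non-ACGT maps to 0 (treated as 'A')
_CODE = np.zeros(256, dtype=np.int64)
for _i, _a in enumerate(b"ACGT"):
    _CODE[_a] = _i


def to_array(seq: str) -> np.ndarray:
    """Encode a DNA string as a uint8 byte array."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def to_string(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def revcomp_array(arr: np.ndarray) -> np.ndarray:
    return _COMP[arr[::-1]]


def revcomp(seq: str) -> str:
    return to_string(revcomp_array(to_array(seq)))


def kmer_codes(arr: np.ndarray, k: int) -> np.ndarray:
    """Packed 2-bit integer codes of all k-mers of ``arr`` (length n-k+1).

    Empty for sequences shorter than k. k must be <= 31 to fit int64.
    """
    if k > 31:
        raise ValueError("k must be <= 31")
    n = arr.size
    if n < k:
        return np.empty(0, dtype=np.int64)
    codes2 = _CODE[arr]
    windows = np.lib.stride_tricks.sliding_window_view(codes2, k)
    weights = (4 ** np.arange(k - 1, -1, -1)).astype(np.int64)
    return windows @ weights


def kmer_set(seq_or_arr, k: int) -> frozenset:
    """Distinct k-mers of a sequence as a frozenset of packed codes."""
    arr = to_array(seq_or_arr) if isinstance(seq_or_arr, str) else seq_or_arr
    return frozenset(kmer_codes(arr, k).tolist())


def canonical_kmer_codes(arr: np.ndarray, k: int) -> np.ndarray:
    """Strand-canonical k-mer codes: elementwise min of forward and RC codes."""
    fwd = kmer_codes(arr, k)
    rev = kmer_codes(revcomp_array(arr), k)[::-1]
    if fwd.size == 0:
        return fwd
    return np.minimum(fwd, rev)


def minimizers(arr: np.ndarray, k: int, w: int) -> np.ndarray:
    """Distinct windowed minima of canonical k-mer codes (bucketing sketch)."""
    codes = canonical_kmer_codes(arr, k)
    if codes.size == 0:
        return codes
    if codes.size <= w:
        return np.unique(codes.min(keepdims=True))
    wins = np.lib.stride_tricks.sliding_window_view(codes, w)
    return np.unique(wins.min(axis=1))


class KmerIndex:
    """Sorted-array index of the k-mer positions of one target sequence."""

    def __init__(self, arr: np.ndarray, k: int):
        self.k = k
        self.length = arr.size
        codes = kmer_codes(arr, k)
        order = np.argsort(codes, kind="stable")
        self._codes = codes[order]
        self._positions = order.astype(np.int64)

    def diagonals(self, query_arr: np.ndarray) -> np.ndarray:
        """Distinct diagonals (target_pos - query_pos) sharing a k-mer with query."""
        qcodes = kmer_codes(query_arr, self.k)
        if qcodes.size == 0 or self._codes.size == 0:
            return np.empty(0, dtype=np.int64)
        lo = np.searchsorted(self._codes, qcodes, side="left")
        hi = np.searchsorted(self._codes, qcodes, side="right")
        counts = hi - lo
        hit_q = np.nonzero(counts)[0]
        if hit_q.size == 0:
            return np.empty(0, dtype=np.int64)
        parts = [self._positions[lo[q]:hi[q]] - q for q in hit_q]
        return np.unique(np.concatenate(parts))
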