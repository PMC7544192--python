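"""Packed-integer k-mer extraction.

k-mers are packed two bits per base (A=0, C=1, G=2, T=3) into int64, so k
must satisfy 2k <= 62; odd k also avoids self-reverse-complement k-mers.
Counting is strand-independent: each window contributes the numeric minimum
of its forward and reverse-complement encoding ("canonical" k-mer).
Windows containing N are skipped.  The inner loops are numba-compiled.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_CODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_BASES = "ACGT"


def encode(seq: str) -> np.ndarray:
    """Map a DNA string to base codes (A=0..T=3, anything else 4)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@njit(cache=True)
def _extract_canonical(codes, offsets, k):  # pragma: no cover - numba
    mask = (np.int64(1) << (2 * k)) - 1
    shift = 2 * (k - 1)
    out = np.empty(codes.shape[0], dtype=np.int64)
    m = 0
    for r in range(offsets.shape[0] - 1):
        f = np.int64(0)
        rc = np.int64(0)
        valid = 0
        for i in range(offsets[r], offsets[r + 1]):
            c = codes[i]
            if c > 3:
                valid = 0
                continue
            f = ((f << 2) | c) & mask
            rc = (rc >> 2) | (np.int64(3 - c) << shift)
            valid += 1
            if valid >= k:
                out[m] = f if f < rc else rc
                m += 1
    return out[:m]


@njit(cache=True)
def _revcomp_ints(vals, k):  # pragma: no cover - numba
    out = np.empty_like(vals)
    for i in range(vals.shape[0]):
        v = vals[i]
        rc = np.int64(0)
        for _ in range(k):
            rc = (rc << 2) | (3 - (v & 3))
            v >>= 2
        out[i] = rc
    return out


def canonical_kmer_counts(seqs: list[str], k: int) -> tuple[np.ndarray, np.ndarray]:
    """Count canonical k-mers over a list of sequences.

    Returns (sorted unique canonical k-mer ints, counts).  Sequences
    shorter than k and windows containing N contribute nothing.
    """
    if k % 2 == 0:
        raise ValueError("k must be odd (even k makes canonical strand ambiguous)")
    if 2 * k > 62:
        raise ValueError("k too large for 2-bit int64 packing (k <= 31)")
    if not seqs:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    lengths = np.fromiter((len(s) for s in seqs), dtype=np.int64, count=len(seqs))
    offsets = np.zeros(len(seqs) + 1, dtype=np.int64)
    np.cumsum(lengths, out=offsets[1:])
    codes = _CODE[np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8)]
    kmers = _extract_canonical(codes, offsets, k)
    if kmers.size == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    uniq, counts = np.unique(kmers, return_counts=True)
    return uniq, counts.astype(np.int64)


def revcomp_int(vals: np.ndarray, k: int) -> np.ndarray:
    """Reverse-complement packed k-mers."""
    return _revcomp_ints(np.ascontiguousarray(vals, dtype=np.int64), k)


def kmer_to_str(v: int, k: int) -> str:
    return "".join(_BASES[(int(v) >> (2 * (k - 1 - i))) & 3] for i in range(k))


def str_to_kmer(s: str) -> int:
    v = 0
    for ch in s:
        c = int(_CODE[ord(ch)])
        if c > 3:
            raise ValueError(f"non-ACGT base in k-mer: {s!r}")
        v = (v << 2) | c
    return v
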