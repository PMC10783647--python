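"""2-bit sequence encoding and canonical k-mer machinery.

Everything downstream that touches k-mers (the anchor aligner, the
female-read exclusion test, seed finding) goes through these helpers so
that a k-mer is always represented the same way: a ``uint64`` packing of
the 2-bit codes A=0, C=1, G=2, T=3, canonicalized as the lexicographic
minimum of the k-mer and its reverse complement. Bases other than ACGT
(N, separators) receive code 4 and invalidate every window covering them.
"""

from __future__ import annotations

import numpy as np

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i  # lower case

_BASES = np.frombuffer(b"ACGT N", dtype=np.uint8)  # index 4 -> 'N' via clip


def encode(seq: str | bytes) -> np.ndarray:
    """Encode a sequence into uint8 codes (A0 C1 G2 T3, other 4)."""
    if isinstance(seq, str):
        seq = seq.encode("ascii")
    return _CODE[np.frombuffer(seq, dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    out = np.where(codes > 3, np.uint8(ord("N")), _BASES[np.minimum(codes, 3)])
    return out.tobytes().decode("ascii")


def complement_codes(codes: np.ndarray) -> np.ndarray:
    comp = (3 - codes.astype(np.int16)).astype(np.uint8)
    comp[codes > 3] = 4
    return comp


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return complement_codes(codes)[::-1].copy()


def revcomp(seq: str) -> str:
    return decode(revcomp_codes(encode(seq)))


def kmer_values(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Forward-strand packed k-mer values and a validity mask.

    Returns ``(values, valid)`` of length ``n - k + 1``. Windows covering
    a non-ACGT base are flagged invalid; their packed value is garbage and
    must be masked by the caller.
    """
    n = codes.size
    m = n - k + 1
    if m <= 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    kv = np.zeros(m, dtype=np.uint64)
    masked = np.minimum(codes, 3).astype(np.uint64)
    for i in range(k):
        kv <<= np.uint64(2)
        kv |= masked[i : i + m]
    bad = (codes > 3).astype(np.int64)
    csum = np.concatenate(([0], np.cumsum(bad)))
    valid = (csum[k:] - csum[:-k]) == 0
    return kv, valid


def canonical_kmer_values(
    codes: np.ndarray, k: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Canonical packed k-mers.

    Returns ``(canon, fwd_is_canon, valid)``: the canonical value per
    window, whether the forward orientation is the canonical one, and the
    validity mask.
    """
    kv, valid = kmer_values(codes, k)
    m = kv.size
    if m == 0:
        return kv, np.empty(0, dtype=bool), valid
    comp = np.minimum(3 - np.minimum(codes, 3), 3).astype(np.uint64)
    rkv = np.zeros(m, dtype=np.uint64)
    for j in range(k):
        rkv |= comp[j : j + m] << np.uint64(2 * j)
    fwd = kv <= rkv
    canon = np.where(fwd, kv, rkv)
    return canon, fwd, valid
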