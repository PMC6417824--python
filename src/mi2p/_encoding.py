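"""Vectorized 2-bit DNA encoding and canonical k-mer window extraction.

Every heavy path in the package (k-mer counting, read voting, the built-in
read mapper) runs on int64 k-mer codes rather than strings.  A k-mer over
{A,C,G,T} is encoded base-by-base with A=0, C=1, G=2, T=3 as a base-4
integer (most significant digit first), so numeric order of codes equals
lexicographic order of the k-mer strings.  Any other symbol gets the
sentinel code 4 and invalidates every window that covers it.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

# 4 marks "not A/C/G/T"; windows containing it are dropped.
INVALID = 4

_CODE = np.full(256, INVALID, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i  # lowercase

_LETTER = np.frombuffer(b"ACGTN", dtype=np.uint8)

MAX_K = 31  # 4**31 < 2**63


def encode(seq: str | bytes) -> np.ndarray:
    """Encode a DNA string to uint8 base codes (A=0,C=1,G=2,T=3, other=4)."""
    if isinstance(seq, str):
        seq = seq.encode("ascii")
    return _CODE[np.frombuffer(seq, dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    """Inverse of :func:`encode` for a 1-D base-code array."""
    return _LETTER[codes].tobytes().decode("ascii")


def concat_encode(seqs: Iterable[str | bytes]) -> tuple[np.ndarray, np.ndarray]:
    """Encode sequences into one array separated by sentinel bases.

    Returns ``(codes, starts)`` where ``starts[i]`` is the offset of sequence
    *i* in ``codes``; a single INVALID separator sits between consecutive
    sequences so no window spans two of them.
    """
    parts: list[np.ndarray] = []
    starts: list[int] = []
    sep = np.array([INVALID], dtype=np.uint8)
    pos = 0
    for s in seqs:
        e = encode(s)
        starts.append(pos)
        parts.append(e)
        parts.append(sep)
        pos += e.size + 1
    if not parts:
        return np.empty(0, dtype=np.uint8), np.empty(0, dtype=np.int64)
    return np.concatenate(parts), np.asarray(starts, dtype=np.int64)


def window_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Canonical codes for all length-k windows of a base-code array.

    Returns ``(canon, valid)`` with one entry per window start position
    (``codes.size - k + 1`` of them).  ``canon`` is the smaller of the
    forward and reverse-complement base-4 codes; ``valid`` is False for
    windows covering a non-ACGT base.
    """
    if not 1 <= k <= MAX_K:
        raise ValueError(f"k must be in [1, {MAX_K}], got {k}")
    n = codes.size
    if n < k:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    c = codes.astype(np.int64)
    pw = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    win = np.lib.stride_tricks.sliding_window_view(c, k)
    fwd = win @ pw
    # reverse complement: complement each base, read the window backwards
    comp = 3 - c
    rc = np.lib.stride_tricks.sliding_window_view(comp, k) @ pw[::-1]
    canon = np.minimum(fwd, rc)
    bad = (codes == INVALID).astype(np.int64)
    cs = np.concatenate(([0], np.cumsum(bad)))
    valid = (cs[k:] - cs[:-k]) == 0
    return canon, valid


def kmer_to_code(kmer: str) -> int:
    """Base-4 integer code of a k-mer (A=0..T=3, big-endian)."""
    e = encode(kmer)
    if (e == INVALID).any():
        raise ValueError(f"k-mer contains non-ACGT bases: {kmer!r}")
    k = e.size
    return int(e.astype(np.int64) @ (4 ** np.arange(k - 1, -1, -1, dtype=np.int64)))


def codes_to_kmers(codes: np.ndarray, k: int) -> list[str]:
    """Decode an int64 code array back to k-mer strings."""
    codes = np.asarray(codes, dtype=np.int64)
    out = np.empty((codes.size, k), dtype=np.uint8)
    c = codes.copy()
    for j in range(k - 1, -1, -1):
        out[:, j] = _LETTER[c % 4]
        c //= 4
    return [s.decode("ascii") for s in out.view(f"S{k}").ravel()]


def canonical_codes_of_seqs(seqs: Sequence[str], k: int) -> np.ndarray:
    """Sorted unique canonical k-mer codes occurring in any of ``seqs``."""
    codes, _ = concat_encode(seqs)
    canon, valid = window_codes(codes, k)
    return np.unique(canon[valid])
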