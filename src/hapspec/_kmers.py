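"""Vectorised 2-bit k-mer machinery.

A k-mer of k <= 31 packs into a uint64 (2 bits per base, first base most
significant).  Windows containing any non-ACGT character are dropped.  The
canonical form of a word is the lexicographic minimum of the word and its
reverse complement, so both strands collapse to one key.
"""

from __future__ import annotations

import numpy as np

# A,C,G,T -> 0..3; everything else (incl. N) -> 4 (invalid sentinel)
_BASE_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i
    _BASE_CODE[_b + 32] = _i  # lowercase

_CODE_BASE = np.frombuffer(b"ACGTN", dtype=np.uint8)

MAX_K = 31  # 2k bits must fit a uint64 with headroom


def encode(seq: str | bytes) -> np.ndarray:
    """Encode a sequence to a uint8 array of base codes (4 = invalid)."""
    if isinstance(seq, str):
        seq = seq.encode("ascii")
    return _BASE_CODE[np.frombuffer(seq, dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    """Inverse of :func:`encode`; code 4 decodes to N."""
    return _CODE_BASE[np.minimum(codes, 4)].tobytes().decode("ascii")


def window_codes(arr: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Forward and reverse-complement codes for every valid k-window.

    Returns ``(fwd, rev, starts)`` where ``starts`` are the window start
    offsets into ``arr`` that contain no invalid base.
    """
    if not 1 <= k <= MAX_K:
        raise ValueError(f"k must be in [1, {MAX_K}], got {k}")
    n = arr.size - k + 1
    if n <= 0:
        e = np.empty(0, dtype=np.uint64)
        return e, e.copy(), np.empty(0, dtype=np.int64)
    invalid = arr >= 4
    cs = np.concatenate(([0], np.cumsum(invalid)))
    good = (cs[k:] - cs[:-k]) == 0
    av = arr.astype(np.uint64)
    av[invalid] = 0
    comp = np.uint64(3) - av
    fwd = np.zeros(n, dtype=np.uint64)
    rev = np.zeros(n, dtype=np.uint64)
    two = np.uint64(2)
    for i in range(k):
        fwd = (fwd << two) | av[i : i + n]
        rev |= comp[i : i + n] << np.uint64(2 * i)
    starts = np.flatnonzero(good)
    return fwd[starts], rev[starts], starts


def canonical_window_codes(arr: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Canonical (strand-collapsed) codes for every valid k-window."""
    fwd, rev, starts = window_codes(arr, k)
    return np.minimum(fwd, rev), starts


def concat_reads(seqs: list[str]) -> np.ndarray:
    """Encode many sequences into one array, separated by the invalid code.

    The separator guarantees no window spans two reads.
    """
    joined = b"N".join(s.encode("ascii") for s in seqs)
    return _BASE_CODE[np.frombuffer(joined, dtype=np.uint8)]


def multiplicity_histogram(
    seqs: list[str], k: int, canonical: bool = True, cap: int = 10_000
) -> dict[int, int]:
    """Count k-mers across ``seqs`` and histogram their multiplicities.

    Multiplicities above ``cap`` accumulate in the cap bin (the convention
    used by k-mer counters' ``histo`` output with an upper bound).
    """
    arr = concat_reads(seqs)
    if canonical:
        codes, _ = canonical_window_codes(arr, k)
    else:
        codes, _, _ = window_codes(arr, k)
    if codes.size == 0:
        return {}
    _, counts = np.unique(codes, return_counts=True)
    counts = np.minimum(counts, cap)
    hist = np.bincount(counts)
    return {int(m): int(n) for m, n in enumerate(hist) if m >= 1 and n > 0}


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGTN string (N maps to N)."""
    return seq.translate(_RC_TABLE)[::-1]


_RC_TABLE = str.maketrans("ACGTNacgtn", "TGCANtgcan")
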