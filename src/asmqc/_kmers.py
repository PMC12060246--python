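"""Vectorised k-mer encoding, canonicalisation and hashing.

Shared by the per-contig uniqueness statistics and the MinHash sketches.
Sequences are encoded base-per-byte (A=0, C=1, G=2, T=3, anything else
invalid); k-mers are packed into 64-bit integers (2 bits/base, so k <= 32)
and optionally strand-collapsed to the minimum of a k-mer and its reverse
complement.
"""

from __future__ import annotations

import numpy as np

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i  # lowercase

_U2 = np.uint64(2)
_SPLITMIX_GAMMA = np.uint64(0x9E3779B97F4A7C15)
_MIX1 = np.uint64(0xBF58476D1CE4E5B9)
_MIX2 = np.uint64(0x94D049BB133111EB)


def encode(sequence: str) -> np.ndarray:
    """Encode a sequence as uint8 codes; 255 marks non-ACGT bases."""
    raw = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    return _CODE[raw]


def kmer_codes(sequence: str, k: int, canonical: bool = True) -> np.ndarray:
    """Packed integer codes of every valid k-mer window of *sequence*.

    Windows containing a non-ACGT base are skipped. With ``canonical`` each
    code is the lexicographic minimum of the k-mer and its reverse
    complement (under the A<C<G<T order induced by the 2-bit encoding).
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if k > 32:
        raise ValueError(f"k must be <= 32 to fit 64-bit codes, got {k}")
    n = len(sequence)
    if n < k:
        raise ValueError(f"sequence length {n} shorter than k={k}")
    codes = encode(sequence)
    valid = (codes < 4).astype(np.int32)
    # window is valid iff all k bases are valid
    csum = np.concatenate(([0], np.cumsum(valid)))
    win_valid = (csum[k:] - csum[:-k]) == k

    n_win = n - k + 1
    codes64 = codes.astype(np.uint64)
    # mask invalid bases to 0 so shifts stay in range; masked out afterwards
    codes64[codes >= 4] = 0
    fwd = np.zeros(n_win, dtype=np.uint64)
    for j in range(k):
        fwd = (fwd << _U2) | codes64[j : j + n_win]
    if not canonical:
        return fwd[win_valid]
    rc = np.zeros(n_win, dtype=np.uint64)
    comp = np.uint64(3) - codes64
    for j in range(k):
        rc |= comp[j : j + n_win] << np.uint64(2 * j)
    return np.minimum(fwd, rc)[win_valid]


def mix64(values: np.ndarray) -> np.ndarray:
    """SplitMix64 finaliser: a fixed, platform-independent 64-bit hash."""
    with np.errstate(over="ignore"):
        z = values.astype(np.uint64) + _SPLITMIX_GAMMA
        z = (z ^ (z >> np.uint64(30))) * _MIX1
        z = (z ^ (z >> np.uint64(27))) * _MIX2
        return z ^ (z >> np.uint64(31))


def revcomp(sequence: str) -> str:
    return sequence.translate(str.maketrans("ACGTacgtNn", "TGCAtgcaNn"))[::-1]
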