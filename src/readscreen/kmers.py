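"""Canonical k-mer extraction and seeded 64-bit hashing.

Every screen-building method and the read classifier share this machinery.
K-mers are compared strand-neutrally: each window is replaced by its
*canonical* form, the lexicographically smaller of the k-mer and its reverse
complement. Canonical k-mers are packed into 64-bit integers (2 bits per
base, first base in the highest bits, so integer order equals lexicographic
order) and passed through an invertible seeded mixing function. Because the
mix is a bijection on 64-bit values, distinct k-mers never collide for a
fixed seed and k <= 31.

A test-only *identity* mode (``seed=None``) skips the mixing step and returns
the packed 2-bit encoding itself, which makes exact brute-force oracles
possible (A=0, C=1, G=2, T=3, big-endian).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

MAX_K = 31  # a k-mer must pack into 62 bits of a uint64

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCATGCA")

# base -> 2-bit code; anything outside ACGT/acgt marks the window invalid
_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i
for _i, _b in enumerate(b"acgt"):
    _ENCODE[_b] = _i

_DECODE = np.frombuffer(b"ACGT", dtype=np.uint8)


class InvalidKmerError(ValueError):
    """Raised when a k-mer contains a non-ACGT character."""


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (case preserved per-base)."""
    return seq.translate(_COMPLEMENT)[::-1]


def canonical_form(kmer: str) -> str:
    """Return the lexicographically smaller of ``kmer`` and its reverse complement.

    Idempotent and strand-neutral: ``canonical_form(x) ==
    canonical_form(reverse_complement(x))``.
    """
    kmer = kmer.upper()
    if any(c not in "ACGT" for c in kmer):
        raise InvalidKmerError(f"non-ACGT character in k-mer {kmer!r}")
    rc = reverse_complement(kmer)
    return kmer if kmer <= rc else rc


def _mix64(x: np.ndarray | np.uint64) -> np.ndarray | np.uint64:
    # splitmix64 finalizer: invertible, well-mixed; wraparound is intended
    x = np.uint64(x) if np.isscalar(x) else x
    with np.errstate(over="ignore"):
        x ^= x >> np.uint64(30)
        x *= np.uint64(0xBF58476D1CE4E5B9)
        x ^= x >> np.uint64(27)
        x *= np.uint64(0x94D049BB133111EB)
        x ^= x >> np.uint64(31)
    return x


def _seed_key(seed: int) -> np.uint64:
    with np.errstate(over="ignore"):
        base = np.uint64(seed & 0xFFFFFFFFFFFFFFFF) + np.uint64(0x9E3779B97F4A7C15)
    return _mix64(base)


def encode_sequence(seq: str) -> np.ndarray:
    """2-bit codes of a sequence; 255 where the base is not ACGT."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _ENCODE[raw]


def decode_packed(packed: int, k: int) -> str:
    """Inverse of the 2-bit packing: packed uint64 -> k-mer string."""
    codes = (packed >> (2 * np.arange(k - 1, -1, -1, dtype=np.uint64))) & 3
    return _DECODE[codes.astype(np.intp)].tobytes().decode("ascii")


def hash_kmer(canon: str, seed: int | None) -> int:
    """Seeded 64-bit hash of a canonical k-mer.

    ``seed=None`` selects identity mode: the result is the plain 2-bit
    big-endian packing of the k-mer (so ``hash_kmer("AAA", None) == 0``).
    """
    k = len(canon)
    if k > MAX_K:
        raise ValueError(f"k={k} exceeds the supported maximum of {MAX_K}")
    codes = encode_sequence(canon)
    if np.any(codes > 3):
        raise InvalidKmerError(f"non-ACGT character in k-mer {canon!r}")
    packed = np.uint64(0)
    for c in codes:
        packed = (packed << np.uint64(2)) | np.uint64(c)
    if seed is None:
        return int(packed)
    return int(_mix64(packed ^ _seed_key(seed)))


def kmer_hashes(seq: str, k: int, seed: int | None) -> tuple[np.ndarray, np.ndarray]:
    """Hashes of all valid canonical k-mers of ``seq``, with their positions.

    Returns ``(positions, hashes)``: 0-based start offsets (int64) of every
    window free of non-ACGT characters, and the corresponding seeded hashes
    (uint64), ordered by position. Windows containing an ambiguity code are
    skipped. A sequence shorter than k yields empty arrays.
    """
    if not 1 <= k <= MAX_K:
        raise ValueError(f"k must be in [1, {MAX_K}], got {k}")
    n = len(seq)
    if n < k:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.uint64)
    codes = encode_sequence(seq)
    bad = codes > 3
    codes = np.where(bad, 0, codes).astype(np.uint64)
    npos = n - k + 1

    fwd = np.zeros(npos, dtype=np.uint64)
    rev = np.zeros(npos, dtype=np.uint64)
    three = np.uint64(3)
    for j in range(k):
        fwd = (fwd << np.uint64(2)) | codes[j : j + npos]
        rev |= (three - codes[j : j + npos]) << np.uint64(2 * j)
    canon = np.minimum(fwd, rev)

    if bad.any():
        cs = np.concatenate(([0], np.cumsum(bad)))
        valid = (cs[k:] - cs[:-k]) == 0
        positions = np.nonzero(valid)[0].astype(np.int64)
        canon = canon[valid]
    else:
        positions = np.arange(npos, dtype=np.int64)

    if seed is None:
        return positions, canon
    return positions, _mix64(canon ^ _seed_key(seed))


@dataclass(frozen=True)
class KmerRecord:
    """One extracted k-mer: start offset, canonical string, seeded hash."""

    position: int
    canon: str
    hash: int


def extract_kmers(seq: str, k: int, seed: int | None = None) -> list[KmerRecord]:
    """All valid k-mers of ``seq`` as records, ordered by position.

    Record-level convenience API over :func:`kmer_hashes`; the screen
    builders use the array form directly.
    """
    seq = seq.upper()
    positions, hashes = kmer_hashes(seq, k, seed)
    return [
        KmerRecord(int(p), canonical_form(seq[p : p + k]), int(h))
        for p, h in zip(positions, hashes)
    ]
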