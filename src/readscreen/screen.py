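"""Screen construction: sized sketches and samples of reference genomes.

A *screen* is a collection of reduced representations, one per potential
source genome, against which query reads are classified. Five selection
strategies are supported:

- ``uniform``          — systematic sampling, one k-mer every n/s bases;
- ``minhash``          — bottom-s sketch (s smallest hash values, single
                         hash function, Mash-style);
- ``weighted_minhash`` — bottom-s sketch plus per-hash discriminativeness
                         weights computed across the whole screen;
- ``order_minhash``    — bottom-s sketch plus genome-position ordering,
                         grouped into sublists of length L;
- ``minimizer``        — windowed minimizers with window w = 2n/s.

All methods are sized by the same rule: to expect ``t`` stored hashes shared
with an error-free stretch of a read of length R from a genome of n bp, at
per-base error rate e and k-mer length k,

    s = ceil( t * n / (R * (1 - e)^k) )

where the ``1/(1-e)^k`` factor oversamples to compensate for k-mers broken
by sequencing error.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Literal, Sequence

import numpy as np

from .kmers import MAX_K, kmer_hashes

MethodName = Literal["uniform", "minhash", "weighted_minhash", "order_minhash", "minimizer"]

METHODS: tuple[str, ...] = (
    "uniform",
    "minhash",
    "weighted_minhash",
    "order_minhash",
    "minimizer",
)

_U64_MAX = np.uint64(0xFFFFFFFFFFFFFFFF)


@dataclass(frozen=True)
class ScreenParams:
    """Experiment parameters that govern sketch/sample sizing.

    hash_seed=None selects the test-only identity hash (see kmers module).
    """

    k: int = 21
    read_length: int = 10_000
    error_rate: float = 0.01
    target_matches: int = 100
    hash_seed: int | None = 0

    def __post_init__(self) -> None:
        if not 1 <= self.k <= MAX_K:
            raise ValueError(f"k must be in [1, {MAX_K}]")
        if self.read_length < self.k:
            raise ValueError("read_length must be >= k")
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must be in [0, 1)")
        if self.target_matches < 1:
            raise ValueError("target_matches must be >= 1")


@dataclass(frozen=True)
class MethodParams:
    """Which selection strategy to use, plus its method-specific knobs.

    ``sublist_length`` (L) applies to order_minhash; ``weight_multiplier``
    (M) boosts screen-unique hashes under weighted_minhash (M=1 reproduces
    plain weighted MinHash). The minimizer window multiplier is fixed at 2:
    minimizer spacing is uniform on [0, w), so a window of 2n/s yields about
    s selected k-mers.
    """

    method: str = "minhash"
    sublist_length: int | None = None
    weight_multiplier: int = 1
    window_multiplier: int = 2

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; choose from {METHODS}")
        if self.method == "order_minhash":
            if self.sublist_length is None or self.sublist_length < 2:
                raise ValueError("order_minhash requires sublist_length >= 2")
        if self.weight_multiplier < 1:
            raise ValueError("weight_multiplier must be >= 1")


@dataclass
class GenomeSketch:
    """One genome's reduced representation.

    ``hashes`` is a sorted uint64 array of the selected canonical k-mer
    hashes. ``weights`` (weighted_minhash only) is aligned with ``hashes``.
    ``positions`` (order_minhash only) holds the selected (position, hash)
    pairs ordered by concatenated genome coordinate, and ``sublists`` the
    derived consecutive runs of L hashes.
    """

    genome_id: str
    genome_size: int
    hashes: np.ndarray
    weights: np.ndarray | None = None
    positions: np.ndarray | None = None  # shape (m, 2): position, hash
    sublists: list[tuple[int, ...]] | None = None

    @property
    def hash_set(self) -> set[int]:
        return set(int(h) for h in self.hashes)

    def position_order(self) -> tuple[np.ndarray, np.ndarray]:
        """(positions, hashes) of the selected k-mers ordered by position."""
        if self.positions is None:
            raise ValueError(f"sketch {self.genome_id!r} stores no positions")
        pos = np.ascontiguousarray(self.positions[:, 0])
        h = np.ascontiguousarray(self.positions[:, 1]).view(np.uint64)
        return pos, h

    def __len__(self) -> int:
        return len(self.hashes)


@dataclass
class Screen:
    """A collection of genome sketches plus the parameters that built them."""

    params: ScreenParams
    method: MethodParams
    sketches: list[GenomeSketch] = field(default_factory=list)

    @property
    def genome_ids(self) -> list[str]:
        return [sk.genome_id for sk in self.sketches]

    def __len__(self) -> int:
        return len(self.sketches)

    def sketch(self, genome_id: str) -> GenomeSketch:
        for sk in self.sketches:
            if sk.genome_id == genome_id:
                return sk
        raise KeyError(genome_id)


def sketch_size(params: ScreenParams, genome_size: int) -> int:
    """Number of k-mers to store for a genome of ``genome_size`` bp.

    Computed in exact rational arithmetic as
    ``ceil(t * n / (R * (1 - e)^k))`` and capped at the number of k-mer
    start positions, n - k + 1.
    """
    if not 0 <= params.error_rate < 1:
        raise ValueError("error_rate must be in [0, 1)")
    n = genome_size
    exact = (
        Fraction(params.target_matches)
        * n
        / (Fraction(params.read_length) * (1 - Fraction(params.error_rate)) ** params.k)
    )
    s = math.ceil(exact)
    return min(s, max(n - params.k + 1, 1))


def _genome_arrays(
    records: Sequence[str], k: int, seed: int | None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Positions (concatenated coordinates), hashes, and record offsets."""
    positions, hashes = [], []
    offsets = np.zeros(len(records), dtype=np.int64)
    off = 0
    for i, rec in enumerate(records):
        offsets[i] = off
        p, h = kmer_hashes(rec, k, seed)
        positions.append(p + off)
        hashes.append(h)
        off += len(rec)
    if positions:
        return np.concatenate(positions), np.concatenate(hashes), offsets
    return np.empty(0, np.int64), np.empty(0, np.uint64), offsets


def _apportion(sizes: Sequence[int], s: int) -> list[int]:
    """Split s selections across records proportionally to their lengths."""
    total = sum(sizes)
    if total == 0:
        return [0] * len(sizes)
    quotas = [s * sz / total for sz in sizes]
    base = [math.floor(q) for q in quotas]
    short = s - sum(base)
    # largest remainders get the leftover slots
    order = sorted(range(len(sizes)), key=lambda i: quotas[i] - base[i], reverse=True)
    for i in order[:short]:
        base[i] += 1
    return base


def build_uniform(records: Sequence[str], s: int, params: ScreenParams, genome_id: str = "") -> GenomeSketch:
    """Systematic sample: a k-mer every n/s bases.

    Selection positions are the arithmetic progression round(i*n/s); within
    multi-record genomes the s slots are apportioned to records by length
    and the progression applied per record. A selected window containing an
    ambiguity code is replaced by the nearest valid window to its right.
    """
    if s < 1:
        raise ValueError("s must be >= 1")
    k, seed = params.k, params.hash_seed
    n = sum(len(r) for r in records)
    chosen: list[np.ndarray] = []
    n_valid_total = 0
    for rec, s_r in zip(records, _apportion([len(r) for r in records], s)):
        pos, hashes = kmer_hashes(rec, k, seed)
        n_valid_total += len(pos)
        if s_r == 0 or len(pos) == 0:
            continue
        if s_r >= len(pos):  # saturation: every valid k-mer
            chosen.append(hashes)
            continue
        n_r = len(rec)
        targets = np.minimum(
            np.round(np.arange(s_r) * n_r / s_r).astype(np.int64), n_r - k
        )
        idx = np.searchsorted(pos, targets)  # nearest valid window to the right
        idx = idx[idx < len(pos)]
        chosen.append(hashes[np.unique(idx)])
    if s > n_valid_total:
        warnings.warn(
            f"requested {s} uniform samples but only {n_valid_total} valid "
            f"k-mer windows exist; returning all of them",
            stacklevel=2,
        )
    all_h = np.unique(np.concatenate(chosen)) if chosen else np.empty(0, np.uint64)
    return GenomeSketch(genome_id=genome_id, genome_size=n, hashes=all_h)


def _bottom_s(
    records: Sequence[str], s: int, params: ScreenParams, keep_positions: bool
) -> tuple[np.ndarray, np.ndarray | None, int]:
    """Bottom-s distinct hashes (and first-occurrence positions) in one pass.

    Streams the genome in chunks, holding at most s + chunk hashes at a
    time — the memory contract of a bounded max-heap without its constant
    factors.
    """
    k, seed = params.k, params.hash_seed
    cur_h = np.empty(0, np.uint64)
    cur_p = np.empty(0, np.int64)
    chunk = max(4 * s, 1 << 16)
    off = 0
    for rec in records:
        pos, hashes = kmer_hashes(rec, k, seed)
        pos = pos + off
        off += len(rec)
        for lo in range(0, len(hashes), chunk):
            h = hashes[lo : lo + chunk]
            p = pos[lo : lo + chunk]
            merged_h = np.concatenate([cur_h, h])
            merged_p = np.concatenate([cur_p, p])
            uh, first = np.unique(merged_h, return_index=True)
            # cur precedes the chunk, so first occurrence favors the
            # earliest genome position seen so far
            order_p = merged_p[first]
            keep = min(s, len(uh))
            cur_h, cur_p = uh[:keep], order_p[:keep]
    return cur_h, (cur_p if keep_positions else None), off


def build_minhash(records: Sequence[str], s: int, params: ScreenParams, genome_id: str = "") -> GenomeSketch:
    """Bottom-s MinHash sketch: the s smallest distinct hash values."""
    if s < 1:
        raise ValueError("s must be >= 1")
    hashes, _, n = _bottom_s(records, s, params, keep_positions=False)
    return GenomeSketch(genome_id=genome_id, genome_size=n, hashes=hashes)


def build_order_minhash(
    records: Sequence[str], s: int, L: int, params: ScreenParams, genome_id: str = ""
) -> GenomeSketch:
    """Bottom-s sketch with genome-position ordering in sublists of L.

    The selected hashes are sorted by their (first-occurrence) genome
    position and partitioned into floor(s/L) consecutive runs of exactly L;
    a trailing remainder shorter than L is dropped from the sublists (but
    the hashes stay in the sketch).
    """
    if s < L:
        raise ValueError(f"order_minhash needs s >= L (got s={s}, L={L})")
    hashes, pos, n = _bottom_s(records, s, params, keep_positions=True)
    assert pos is not None
    order = np.argsort(pos, kind="stable")
    positions = np.column_stack([pos[order], hashes[order].view(np.int64)])
    ordered_h = hashes[order]
    n_lists = len(ordered_h) // L
    sublists = [
        tuple(int(h) for h in ordered_h[i * L : (i + 1) * L]) for i in range(n_lists)
    ]
    return GenomeSketch(
        genome_id=genome_id,
        genome_size=n,
        hashes=hashes,
        positions=positions,
        sublists=sublists,
    )


def _sliding_min(keys: np.ndarray, w: int) -> np.ndarray:
    """Minimum of every length-w window of ``keys`` (uint64), vectorized.

    Block decomposition: window min = min(suffix-min of the left block,
    prefix-min of the right block).
    """
    n = len(keys)
    if w >= n:
        return np.array([keys.min()], dtype=keys.dtype)
    nwin = n - w + 1
    nblocks = -(-n // w)
    padded = np.full(nblocks * w, _U64_MAX, dtype=np.uint64)
    padded[:n] = keys
    blocks = padded.reshape(nblocks, w)
    pref = np.minimum.accumulate(blocks, axis=1).ravel()
    suff = np.minimum.accumulate(blocks[:, ::-1], axis=1)[:, ::-1].ravel()
    return np.minimum(suff[:nwin], pref[w - 1 : w - 1 + nwin])


def minimizer_window(genome_size: int, s: int, multiplier: int = 2) -> int:
    """Window size w = max(1, floor(multiplier * n / s))."""
    return max(1, (multiplier * genome_size) // s)


def build_minimizer(
    records: Sequence[str], s: int, params: ScreenParams, genome_id: str = "",
    multiplier: int = 2,
) -> GenomeSketch:
    """Windowed minimizers with window w = 2n/s.

    Slides a window of w consecutive valid k-mer positions along each
    record and keeps the k-mer with the smallest hash per window (leftmost
    on ties); the sketch is the distinct set of selected hashes.
    """
    if s < 1:
        raise ValueError("s must be >= 1")
    k, seed = params.k, params.hash_seed
    n = sum(len(r) for r in records)
    w = minimizer_window(n, s, multiplier)
    sel_h: list[np.ndarray] = []
    sel_p: list[np.ndarray] = []
    off = 0
    for rec in records:
        pos, hashes = kmer_hashes(rec, k, seed)
        if len(hashes):
            # rank-compress hashes so (rank, index) packs into one uint64;
            # the sliding min then lands on the leftmost minimal hash
            u, inv = np.unique(hashes, return_inverse=True)
            keys = (inv.astype(np.uint64) << np.uint64(32)) | np.arange(
                len(hashes), dtype=np.uint64
            )
            winmin = np.unique(_sliding_min(keys, w))
            idx = (winmin & np.uint64(0xFFFFFFFF)).astype(np.int64)
            sel_h.append(hashes[idx])
            sel_p.append(pos[idx] + off)
        off += len(rec)
    if sel_h:
        allh = np.concatenate(sel_h)
        allp = np.concatenate(sel_p)
        uh, first = np.unique(allh, return_index=True)
        positions = np.column_stack([allp[first], uh.view(np.int64)])
        order = np.argsort(positions[:, 0], kind="stable")
        positions = positions[order]
    else:
        uh = np.empty(0, np.uint64)
        positions = np.empty((0, 2), np.int64)
    sk = GenomeSketch(genome_id=genome_id, genome_size=n, hashes=uh)
    sk.positions = positions  # kept for gap diagnostics; not used in scoring
    return sk


def annotate_weights(sketches: list[GenomeSketch], M: int = 1) -> None:
    """Attach discriminativeness weights to every sketch, in place.

    weight(h) = G - occ(h), with G the number of genomes in the screen and
    occ(h) the number of sketches containing h; hashes unique to one genome
    (occ=1) have their weight multiplied by M.
    """
    G = len(sketches)
    if G == 0:
        return
    all_h = np.concatenate([sk.hashes for sk in sketches]) if G else np.empty(0, np.uint64)
    uh, counts = np.unique(all_h, return_counts=True)
    for sk in sketches:
        occ = counts[np.searchsorted(uh, sk.hashes)]
        w = (G - occ).astype(np.int64)
        w[occ == 1] *= M
        sk.weights = w


def build_sketch(
    records: Sequence[str],
    s: int,
    method: MethodParams,
    params: ScreenParams,
    genome_id: str = "",
) -> GenomeSketch:
    """Dispatch to the selection strategy for one genome."""
    if method.method == "uniform":
        return build_uniform(records, s, params, genome_id)
    if method.method in ("minhash", "weighted_minhash"):
        return build_minhash(records, s, params, genome_id)
    if method.method == "order_minhash":
        return build_order_minhash(records, s, method.sublist_length, params, genome_id)
    if method.method == "minimizer":
        return build_minimizer(records, s, params, genome_id, method.window_multiplier)
    raise ValueError(f"unknown method {method.method!r}")


def build_screen(
    genomes: Sequence[tuple[str, Sequence[str]]],
    method: MethodParams,
    params: ScreenParams,
) -> Screen:
    """Build a full screen: one sized sketch per genome.

    ``genomes`` is an ordered list of (genome_id, records). Each genome's
    size s comes from :func:`sketch_size` on its total length; for
    weighted_minhash the cross-genome weights are annotated afterwards.
    """
    if not genomes:
        raise ValueError("cannot build a screen from zero genomes")
    sketches = []
    for gid, records in genomes:
        n = sum(len(r) for r in records)
        s = sketch_size(params, n)
        sketches.append(build_sketch(records, s, method, params, genome_id=gid))
    if method.method == "weighted_minhash":
        annotate_weights(sketches, method.weight_multiplier)
    return Screen(params=params, method=method, sketches=sketches)


def estimate_jaccard(a: GenomeSketch, b: GenomeSketch, s: int | None = None) -> float:
    """Mash-style merged bottom-s Jaccard estimate between two sketches.

    Uses x/s' where s' is the merged sketch size min(s, |A ∪ B|) and x the
    number of shared hashes within the bottom-s' of the union; unbiased for
    bottom sketches, unlike the raw |A∩B|/|A∪B| ratio.
    """
    if s is None:
        s = min(len(a.hashes), len(b.hashes))
    union = np.union1d(a.hashes, b.hashes)[:s]
    inter = np.intersect1d(a.hashes, b.hashes, assume_unique=True)
    x = np.intersect1d(union, inter, assume_unique=True).size
    return x / max(len(union), 1)
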