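"""Read classification against flat screens and sketch trees.

A query read is reduced to the set of hashes of all its canonical k-mers
(no read-side sketching) and compared with every stored representation.
The predicted source is the sketch sharing the most hashes with the read;
method-specific secondary scores (summed discriminativeness weights for
weighted MinHash, order agreement for order MinHash) break equal-count
ties before falling back to a seeded random choice. Reads sharing fewer
than ``min_shared`` hashes with every candidate are left unclassified.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

import numpy as np

from .cluster import SketchTree, SketchTreeNode
from .kmers import kmer_hashes
from .screen import GenomeSketch, Screen

UNCLASSIFIED = "UNCLASSIFIED"


@dataclass(frozen=True)
class ReadKmers:
    """A read's k-mer content prepared for scoring.

    ``hashes`` is the sorted distinct hash array; ``order`` holds the same
    hashes in order of first occurrence along the read (needed for
    order-MinHash scoring).
    """

    read_id: str
    hashes: np.ndarray
    order: np.ndarray


def hash_read(seq: str, k: int, seed: int | None, read_id: str = "") -> ReadKmers:
    """Hash every valid canonical k-mer of a read."""
    _, h = kmer_hashes(seq, k, seed)
    uh, first = np.unique(h, return_index=True)
    order = uh[np.argsort(first, kind="stable")]
    return ReadKmers(read_id=read_id, hashes=uh, order=order)


@dataclass
class ClassificationResult:
    """Per-read prediction.

    ``predicted`` is a genome id, a tuple of genome ids (tie-stop subtree),
    or :data:`UNCLASSIFIED`. ``score`` is the primary shared-hash count of
    the winner; ``secondary`` the method-specific tie-break score.
    """

    read_id: str
    predicted: str | tuple[str, ...]
    score: int = 0
    secondary: int = 0
    n_shared: int = 0
    tied_with: list[str] = field(default_factory=list)
    status: str = "classified"  # classified | tie_stopped | unclassified
    n_hash_comparisons: int = 0

    @property
    def is_unclassified(self) -> bool:
        return self.status == "unclassified"


def _lis_length(seq: np.ndarray) -> int:
    """Longest strictly increasing subsequence length (patience sorting)."""
    tails: list[int] = []
    for x in seq:
        i = bisect.bisect_left(tails, x)
        if i == len(tails):
            tails.append(x)
        else:
            tails[i] = x
    return len(tails)


def order_agreement(read_order: np.ndarray, genome_order: np.ndarray) -> int:
    """Order-MinHash agreement between shared hashes of a read and a sketch.

    Both arguments list the *shared* hashes, ordered by read position and by
    stored genome position respectively. The score is the longest common
    subsequence between the two orderings, evaluated in both read
    orientations so that reverse-strand reads are not penalized; since the
    orderings are permutations of one another this is the longest
    monotone (increasing or decreasing) run of genome ranks.
    """
    rank = {int(h): i for i, h in enumerate(genome_order)}
    ranks = np.array([rank[int(h)] for h in read_order], dtype=np.int64)
    if len(ranks) == 0:
        return 0
    return max(_lis_length(ranks), _lis_length(-ranks))


def score_read(
    read: ReadKmers | set[int] | np.ndarray,
    sketch: GenomeSketch,
    method: str = "minhash",
) -> tuple[int, int]:
    """(primary, secondary) similarity of a read to one sketch.

    primary = number of shared hashes for every method. secondary = 0 for
    uniform/minhash/minimizer, the summed weights of shared hashes for
    weighted_minhash, and the order-agreement score for order_minhash.
    """
    if isinstance(read, ReadKmers):
        rh, rorder = read.hashes, read.order
    else:
        rh = np.sort(np.asarray(sorted(int(x) for x in read), dtype=np.uint64))
        rorder = None
    shared_mask = np.isin(rh, sketch.hashes, assume_unique=True)
    primary = int(shared_mask.sum())
    secondary = 0
    if method == "weighted_minhash":
        if sketch.weights is None:
            raise ValueError("sketch has no weights; was the screen built with weighted_minhash?")
        idx = np.searchsorted(sketch.hashes, rh[shared_mask])
        secondary = int(sketch.weights[idx].sum())
    elif method == "order_minhash":
        if sketch.positions is None:
            raise ValueError("sketch has no positions; was the screen built with order_minhash?")
        if rorder is None:
            raise ValueError("order_minhash scoring needs a ReadKmers with read-order information")
        _, gh = sketch.position_order()
        shared = set(int(h) for h in rh[shared_mask])
        g_order = np.array([h for h in gh if int(h) in shared], dtype=np.uint64)
        r_order = np.array([h for h in rorder if int(h) in shared], dtype=np.uint64)
        secondary = order_agreement(r_order, g_order)
    return primary, secondary


class _FlatIndex:
    """Concatenated sorted-hash index over a screen, for fast flat scoring."""

    def __init__(self, screen: Screen) -> None:
        sks = screen.sketches
        hashes = np.concatenate([sk.hashes for sk in sks])
        gidx = np.concatenate(
            [np.full(len(sk.hashes), i, dtype=np.int64) for i, sk in enumerate(sks)]
        )
        order = np.argsort(hashes, kind="stable")
        self.hashes = hashes[order]
        self.gidx = gidx[order]
        if screen.method.method == "weighted_minhash":
            w = np.concatenate([sk.weights for sk in sks])
            self.weights = w[order]
        else:
            self.weights = None
        self.n_genomes = len(sks)
        self.total_hashes = len(self.hashes)

    def shared_counts(self, read_hashes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Per-genome shared-hash counts (and weight sums if weighted)."""
        lo = np.searchsorted(self.hashes, read_hashes, side="left")
        hi = np.searchsorted(self.hashes, read_hashes, side="right")
        counts = hi - lo
        nz = counts > 0
        tot = counts[nz]
        if tot.size == 0:
            zero = np.zeros(self.n_genomes, dtype=np.int64)
            return zero, zero
        starts = lo[nz]
        flat = np.repeat(starts, tot) + (
            np.arange(tot.sum()) - np.repeat(np.cumsum(tot) - tot, tot)
        )
        g = self.gidx[flat]
        primary = np.bincount(g, minlength=self.n_genomes)
        if self.weights is not None:
            wsum = np.bincount(
                g, weights=self.weights[flat].astype(np.float64), minlength=self.n_genomes
            ).astype(np.int64)
        else:
            wsum = np.zeros(self.n_genomes, dtype=np.int64)
        return primary, wsum


def _flat_index(screen: Screen) -> _FlatIndex:
    idx = getattr(screen, "_cached_flat_index", None)
    if idx is None:
        idx = _FlatIndex(screen)
        screen._cached_flat_index = idx  # type: ignore[attr-defined]
    return idx


def classify_flat(
    read: ReadKmers,
    screen: Screen,
    min_shared: int = 1,
    rng: np.random.Generator | None = None,
) -> ClassificationResult:
    """Classify a read against every sketch of a flat screen.

    Winner = max by (shared-hash count, method secondary); residual ties
    are broken uniformly at random with the supplied generator and reported
    in ``tied_with``.
    """
    rng = rng if rng is not None else np.random.default_rng()
    index = _flat_index(screen)
    primary, wsum = index.shared_counts(read.hashes)
    best = int(primary.max()) if primary.size else 0
    if best < min_shared:
        return ClassificationResult(
            read_id=read.read_id,
            predicted=UNCLASSIFIED,
            status="unclassified",
            n_hash_comparisons=index.total_hashes,
        )
    cands = np.nonzero(primary == best)[0]
    method = screen.method.method
    best_secondary = 0
    if len(cands) > 1 and method == "weighted_minhash":
        sec = wsum[cands]
        best_secondary = int(sec.max())
        cands = cands[sec == best_secondary]
    elif len(cands) > 1 and method == "order_minhash":
        sec = np.array(
            [score_read(read, screen.sketches[i], method)[1] for i in cands]
        )
        best_secondary = int(sec.max())
        cands = cands[sec == best_secondary]
    elif method == "weighted_minhash":
        best_secondary = int(wsum[cands[0]])
    winner = int(cands[0]) if len(cands) == 1 else int(rng.choice(cands))
    tied = [screen.sketches[int(i)].genome_id for i in cands] if len(cands) > 1 else []
    return ClassificationResult(
        read_id=read.read_id,
        predicted=screen.sketches[winner].genome_id,
        score=best,
        secondary=best_secondary,
        n_shared=best,
        tied_with=tied,
        status="classified",
        n_hash_comparisons=index.total_hashes,
    )


def _shared_with(read: ReadKmers, node: SketchTreeNode) -> int:
    return int(np.isin(read.hashes, node.hashes, assume_unique=True).sum())


def classify_tree(
    read: ReadKmers,
    tree: SketchTree,
    min_shared: int = 1,
    tie_mode: str = "random",
    rng: np.random.Generator | None = None,
) -> ClassificationResult:
    """Greedy root-to-leaf descent through a sketch tree.

    At each internal node the read is scored against both children and
    descent follows the strict maximum. If neither child reaches
    ``min_shared`` the read is unclassified. On a tie, ``tie_mode='random'``
    picks a seeded random child while ``tie_mode='stop'`` halts and reports
    the tied node's whole subtree of candidate genomes.
    """
    if tie_mode not in ("random", "stop"):
        raise ValueError(f"unknown tie_mode {tie_mode!r}")
    rng = rng if rng is not None else np.random.default_rng()
    node = tree.root
    comparisons = 0
    if node.is_leaf:
        s = _shared_with(read, node)
        comparisons += len(node.hashes)
        if s < min_shared:
            return ClassificationResult(
                read_id=read.read_id, predicted=UNCLASSIFIED, status="unclassified",
                n_hash_comparisons=comparisons,
            )
        return ClassificationResult(
            read_id=read.read_id, predicted=node.genome_ids[0], score=s,
            n_shared=s, n_hash_comparisons=comparisons,
        )
    while not node.is_leaf:
        left, right = node.children
        sl, sr = _shared_with(read, left), _shared_with(read, right)
        comparisons += len(left.hashes) + len(right.hashes)
        if max(sl, sr) < min_shared:
            return ClassificationResult(
                read_id=read.read_id, predicted=UNCLASSIFIED, status="unclassified",
                n_hash_comparisons=comparisons,
            )
        if sl == sr:
            if tie_mode == "stop":
                return ClassificationResult(
                    read_id=read.read_id,
                    predicted=tuple(node.genome_ids),
                    score=sl,
                    n_shared=sl,
                    tied_with=list(node.genome_ids),
                    status="tie_stopped",
                    n_hash_comparisons=comparisons,
                )
            node = left if rng.integers(2) == 0 else right
        else:
            node = left if sl > sr else right
    s = _shared_with(read, node)
    comparisons += len(node.hashes)
    return ClassificationResult(
        read_id=read.read_id, predicted=node.genome_ids[0], score=s, n_shared=s,
        n_hash_comparisons=comparisons,
    )


def classify_grouped(
    read: ReadKmers,
    screen: Screen,
    groups: dict[str, str],
    min_shared: int = 1,
    rng: np.random.Generator | None = None,
) -> tuple[str, ClassificationResult]:
    """Two-level call: group label (e.g. host vs contaminant) + exact source."""
    missing = [g for g in screen.genome_ids if g not in groups]
    if missing:
        raise KeyError(f"genomes missing from the group map: {missing}")
    res = classify_flat(read, screen, min_shared=min_shared, rng=rng)
    if res.is_unclassified:
        return UNCLASSIFIED, res
    return groups[res.predicted], res


def evaluate(
    results: list[ClassificationResult],
    truth: dict[str, str],
    groups: dict[str, str] | None = None,
) -> dict:
    """Accuracy and diagnostic fractions over a classified readset.

    accuracy = correctly classified / total reads; a randomly resolved tie
    counts as correct only when the resolution hit the true genome, and a
    tie-stopped subtree counts as correct when it contains the true genome.
    Unclassified reads count against accuracy. Per-genome accuracies are
    keyed by the true source; group-level accuracy is reported when a
    genome -> group map is given.
    """
    missing = [r.read_id for r in results if r.read_id not in truth]
    if missing:
        raise KeyError(f"reads missing from truth: {missing[:5]}")
    total = len(results)
    n_correct = n_uncl = n_tie = 0
    per_genome: dict[str, list[int]] = {}
    n_group_correct = 0
    for r in results:
        t = truth[r.read_id]
        stats = per_genome.setdefault(t, [0, 0])
        stats[1] += 1
        if r.is_unclassified:
            n_uncl += 1
            continue
        if r.tied_with:
            n_tie += 1
        if isinstance(r.predicted, tuple):
            correct = t in r.predicted
        else:
            correct = r.predicted == t
        if correct:
            n_correct += 1
            stats[0] += 1
        if groups is not None and not isinstance(r.predicted, tuple):
            if groups.get(r.predicted) == groups.get(t):
                n_group_correct += 1
    out = {
        "n_reads": total,
        "accuracy": n_correct / total if total else 0.0,
        "unclassified_fraction": n_uncl / total if total else 0.0,
        "tie_fraction": n_tie / total if total else 0.0,
        "per_genome_accuracy": {
            g: c / n for g, (c, n) in sorted(per_genome.items())
        },
        "per_genome_counts": {g: (c, n) for g, (c, n) in sorted(per_genome.items())},
    }
    if groups is not None:
        out["group_accuracy"] = n_group_correct / total if total else 0.0
    return out
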