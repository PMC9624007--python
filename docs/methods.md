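# Methods

## Problem and model

`readscreen` addresses long-read source attribution: given a set of
candidate reference genomes and a stream of reads, decide which genome each
read came from (or that it came from none of them). Instead of aligning or
indexing whole genomes, each genome is reduced to a *screen element* — a
set of selected canonical k-mer hashes — and a read is attributed to the
element with which it shares the most hashes.

All comparisons are strand-neutral: every k-mer window is replaced by the
lexicographically smaller of itself and its reverse complement before
hashing. Windows containing non-ACGT characters are skipped entirely.
Hashing packs the canonical k-mer into 2 bits per base (first base in the
highest bits, so integer order equals lexicographic order) and applies an
invertible seeded 64-bit mixing finalizer; because the mix is a bijection,
distinct k-mers never collide at a fixed seed, and `k` is limited to 31 so
a k-mer fits in one machine word. A test-only *identity* hash mode returns
the raw 2-bit packing, which makes exact enumeration oracles possible.
Screens record their seed and refuse to be compared across seeds.

## Sizing

The one rule shared by all selection strategies is the screen size. For a
genome of `n` bp, reads of length `R` with per-base error `e`, and a
desired number `t` of shared hashes per read ("target matches"):

    s = ceil( t * n / (R * (1 - e)^k) )

The factor `1/(1-e)^k` compensates for read k-mers broken by sequencing
error: a fraction `(1-e)^k` of k-mers is expected to survive error-free
(81% at e=0.01, k=21; 34% at e=0.05). Ceiling rounding guarantees at least
the target density; the computation is done in exact rational arithmetic
to avoid float boundary effects, and the result is capped at the `n-k+1`
available windows. Defaults (`k=21, R=10000, e=0.01, t=100`) correspond to
HiFi-like reads and store roughly 1% of a genome's k-mers.

## Selection strategies

- **uniform** — positions `round(i*n/s)`, i.e. one k-mer every `n/s`
  bases. For multi-record genomes the `s` slots are apportioned to records
  by length (largest remainders) and the progression applied per record; a
  selected window containing an ambiguity code falls forward to the
  nearest valid window on its right. Guarantees bounded gaps between
  stored k-mers.
- **minhash** — the `s` smallest distinct hash values over the whole
  genome (bottom-s sketch, single hash function). Implemented as a chunked
  stream holding O(s + chunk) values, matching the memory profile of a
  bounded max-heap.
- **weighted_minhash** — bottom-s plus a per-hash weight computed over the
  *whole screen*: `weight(h) = G - occ(h)` with `G` genomes and `occ(h)`
  the number of sketches containing `h`; screen-unique hashes (`occ=1`)
  are additionally multiplied by `M` (default 1). Weights double storage
  by design; they only participate in tie-breaking.
- **order_minhash** — bottom-s plus the genome position of each selected
  hash (first occurrence for repeated k-mers). Positions are sorted and
  partitioned into `floor(s/L)` disjoint consecutive sublists of exactly
  `L` hashes; a trailing remainder is dropped from the sublists but the
  hashes remain scoreable. Circular genomes are treated as linear; only
  sublists spanning the origin would be affected.
- **minimizer** — sliding windows of `w = max(1, floor(2n/s))` consecutive
  valid k-mer positions, keeping the smallest-hash k-mer per window
  (leftmost on ties). Minimizer spacing is uniform on `[0, w)`, i.e. two
  expected minimizers per `w` bases, hence the fixed multiplier of two to
  land near `s` selections. The sliding minimum is computed by block
  decomposition (prefix/suffix minima over `w`-aligned blocks) on a
  rank-and-position composite key, which yields the leftmost minimum
  directly.

## Classification

A read is reduced to the set of *all* its canonical k-mer hashes (no
read-side sketching). Against a flat screen the winner is the sketch
maximizing `(shared count, secondary)`:

- secondary for weighted MinHash = sum of weights of the shared hashes;
- secondary for order MinHash = order agreement: the longest common
  subsequence between the shared hashes ordered by read position and by
  stored genome position. Because both orderings are permutations of the
  same set, this is the longest monotone run of genome-position ranks
  (patience sorting, O(m log m)). The run is evaluated both increasing and
  decreasing so that reverse-strand reads — whose canonical k-mer order is
  exactly reversed — are not penalized; genuine block rearrangements still
  score below the shared count.

Residual ties are broken uniformly at random with a caller-supplied seeded
generator and reported. Reads whose best shared count falls below
`min_shared` are left unclassified; the default is 1 for simulation work
and 5 is the recommended setting for real readsets, where spurious
single-hash matches occur. Flat scoring uses a concatenated sorted-hash
index over the screen (binary search + per-genome count accumulation), so
cost per read scales with the read's distinct hashes times log of the
screen size, and secondaries are only computed among count-tied candidates
(a lower count can never win).

Group-level ("host vs contaminant") calls run flat classification and map
the winning genome through a genome→group table, reporting both levels.

## Sketch tree

For large screens, sketches are hierarchically clustered (average linkage
on pairwise Jaccard distance `1 - |A∩B|/|A∪B|` of the stored hash sets;
ties resolved by insertion order into a strictly binary tree). Leaves
carry the full sketches; each internal node stores the union of its
children's stored hashes, optionally downsampled without replacement:
`constant` mode keeps `|union|/f` at every internal node, `height` mode
keeps `|union|/f^h` at height `h` (compounding toward the root — chosen
over the additive reading of "proportional to height" as the
interpretation that actually bounds tree size), `none` keeps everything.
Per-node RNG streams are derived from (master seed, node id) so subtree
rebuilds are stable; downsampling to zero is clamped to one hash with a
warning.

Classification descends greedily from the root, scoring the read against
both children by shared count and following the strict maximum;
`tie_mode="stop"` halts at a tied node and reports its whole subtree of
candidate genomes (an LCA-style call), `tie_mode="random"` picks a seeded
random child. Weighted/ordered secondaries are not applied at internal
nodes — the stored unions have no per-genome weights or positions — so
tree descent is count-only until the leaf. Greedy descent is not provably
identical to the flat argmax; on dissimilar communities it agrees with
flat classification on essentially all reads (measured in the test suite),
and with `f=1` a parent's shared count always dominates its children's
(containment monotonicity).

## Simulator

The generator emulates two community regimes. *Dissimilar* communities are
independent uniform-random genomes: two random 300 kb genomes share a
negligible fraction of 21-mers, mirroring mock communities of unrelated
organisms. *Clustered* communities add groups derived from a shared random
ancestor by independent per-base substitutions at rate `d` per member, so
two siblings differ at `~2d(1-d)` of sites and share `(1-2d(1-d))^k` of
their k-mers — the regime where classification degrades into tie-breaking.
Reads are drawn with uniform starts in `[0, n-R]`, uniform strand, and
independent per-base substitutions to a different base at the requested
error rate; `round(c*n/R)` reads per genome at coverage `c`. Errors are
substitutions only (an intentional, technology-agnostic simplification;
indels, chimeras, quality profiles and technology error hotspots are not
modeled), genomes are single-contig, and reads never span contig ends.
Consequences for interpretation: passing tests demonstrate the behavior of
the scoring machinery under calibrated similarity structure, not
robustness to indel-dominated error profiles or real strain complexity.

## Numerical and design choices

- Sizing uses exact `Fraction` arithmetic and `ceil`; tests verify against
  an independent symbolic evaluation.
- Bottom-s sketches use set semantics over distinct hashes (Mash-style);
  a repeated k-mer's position is its first occurrence.
- Minimizer window ties: leftmost position wins, deterministically.
- Jaccard between sketches (tree construction) is the direct ratio over
  stored sets; the unbiased merged bottom-s estimator is provided
  separately (`estimate_jaccard`) and used when estimating true k-mer
  Jaccard.
- All randomness (tie-breaks, downsampling, simulation) flows through
  seeded `numpy` generators; equal seeds give byte-identical outputs,
  including serialized screens (provenance records file mtimes, not wall
  clock).
- Degenerate inputs: sequences shorter than k yield empty k-mer lists;
  requesting more uniform samples than valid windows returns all windows
  with a warning; an empty genome list is an error.

## Problem sizes in the test and acceptance runs

The bundled experiments run at desk scale, chosen to keep the full suite
in the minutes range while preserving the regimes of interest: 24 genomes
of 300 kb (community classification, ~200 reads/genome in the acceptance
script, 40/genome in the test suite), a 5 Mb host plus ten 500 kb
contaminants at 5× (1× in tests) coverage for contaminant detection, and
near-identical pairs at 99.9% identity for the hard-community and
novel-genome experiments. Screen sizes follow the sizing rule throughout;
nothing is tuned per experiment.

## Known limitations

- `k ≤ 31` (single-word packing); the accuracy plateau reported for
  20–50-mers makes larger k unnecessary here.
- Weighted MinHash weights are recomputed over the screen when genomes are
  added or removed (hash sets themselves are unaffected).
- Order MinHash scoring is quadratic-free but still the slowest scorer;
  it only runs on count-tied candidates.
- The screen text format stores decimal hashes; it is diffable and
  language-neutral but ~2.4× larger than a binary encoding would be.
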