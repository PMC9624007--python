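"""Hierarchical clustering of sketches into a downsampled sketch tree.

Classifying a read against a flat screen compares it with every genome.
Grouping similar genomes under a binary tree lets classification descend
from the root and prune dissimilar subtrees early. Leaves carry the
original sketches; each internal node carries the union of its children's
hashes, optionally randomly downsampled to keep the total tree size
comparable to the flat screen:

- ``none``     — internal nodes keep the exact union;
- ``constant`` — every internal node keeps floor(|union| / f) hashes;
- ``height``   — a node at height h keeps floor(|union| / f**h) hashes,
                 compounding toward the root.

Downsampling is without replacement with a per-node RNG derived from
(master seed, node id), so rebuilding any subtree is stable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.cluster.hierarchy import ClusterNode, linkage, to_tree
from scipy.spatial.distance import squareform

from .screen import GenomeSketch, Screen


@dataclass(frozen=True)
class TreeParams:
    """Downsampling schedule for internal nodes of the sketch tree."""

    downsample_mode: Literal["none", "constant", "height"] = "none"
    f: float = 1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.downsample_mode not in ("none", "constant", "height"):
            raise ValueError(f"unknown downsample mode {self.downsample_mode!r}")
        if self.f < 1:
            raise ValueError("downsampling factor f must be >= 1")


@dataclass
class SketchTreeNode:
    node_id: int
    children: tuple["SketchTreeNode", "SketchTreeNode"] | tuple[()] = ()
    hashes: np.ndarray = field(default_factory=lambda: np.empty(0, np.uint64))
    genome_ids: tuple[str, ...] = ()
    height: int = 0

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class SketchTree:
    root: SketchTreeNode
    params: TreeParams
    nodes: dict[int, SketchTreeNode]

    @property
    def n_leaves(self) -> int:
        return sum(1 for n in self.nodes.values() if n.is_leaf)

    def to_newick(self) -> str:
        """Newick topology with genome ids as leaf labels."""

        def fmt(node: SketchTreeNode) -> str:
            if node.is_leaf:
                return node.genome_ids[0]
            return "(" + ",".join(fmt(c) for c in node.children) + ")"

        return fmt(self.root) + ";"


def jaccard_distance(a: GenomeSketch, b: GenomeSketch) -> float:
    """1 - |A ∩ B| / |A ∪ B| over the stored hash sets."""
    inter = np.intersect1d(a.hashes, b.hashes, assume_unique=True).size
    union = len(a.hashes) + len(b.hashes) - inter
    if union == 0:
        return 0.0
    return 1.0 - inter / union


def sketch_distance_matrix(screen: Screen) -> np.ndarray:
    """Symmetric pairwise Jaccard-distance matrix over the screen's sketches."""
    sks = screen.sketches
    if len(sks) < 2:
        raise ValueError("need at least 2 sketches to compute distances")
    n = len(sks)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = jaccard_distance(sks[i], sks[j])
    return D


def linkage_tree(distances: np.ndarray) -> ClusterNode:
    """Average-linkage agglomerative clustering; returns the binary merge tree."""
    Z = linkage(squareform(distances, checks=False), method="average")
    return to_tree(Z)


def _node_seed(master: int, node_id: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([master & 0x7FFFFFFF, node_id]))


def build_sketch_tree(screen: Screen, tree: ClusterNode, tree_params: TreeParams) -> SketchTree:
    """Populate the merge tree with (optionally downsampled) hash unions.

    Leaves hold the full, undownsampled sketches; internal nodes hold a
    seeded without-replacement subsample of their children's union sized by
    ``tree_params``. Downsampling never empties a node: the size is clamped
    to 1 with a warning.
    """
    import warnings

    sks = screen.sketches
    nodes: dict[int, SketchTreeNode] = {}

    def visit(cn: ClusterNode) -> SketchTreeNode:
        if cn.is_leaf():
            sk = sks[cn.get_id()]
            node = SketchTreeNode(
                node_id=cn.get_id(),
                hashes=sk.hashes,
                genome_ids=(sk.genome_id,),
                height=0,
            )
            nodes[node.node_id] = node
            return node
        left = visit(cn.get_left())
        right = visit(cn.get_right())
        union = np.union1d(left.hashes, right.hashes)
        height = max(left.height, right.height) + 1
        mode, f = tree_params.downsample_mode, tree_params.f
        if mode == "none" or f == 1:
            keep = len(union)
        elif mode == "constant":
            keep = int(len(union) // f)
        else:  # height
            keep = int(len(union) // (f**height))
        if keep < 1 and len(union) >= 1:
            warnings.warn(
                f"downsampling would empty node {cn.get_id()}; clamping to 1 hash",
                stacklevel=2,
            )
            keep = 1
        if keep < len(union):
            rng = _node_seed(tree_params.rng_seed, cn.get_id())
            sel = rng.choice(len(union), size=keep, replace=False)
            hashes = np.sort(union[np.sort(sel)])
        else:
            hashes = union
        node = SketchTreeNode(
            node_id=cn.get_id(),
            children=(left, right),
            hashes=hashes,
            genome_ids=left.genome_ids + right.genome_ids,
            height=height,
        )
        nodes[node.node_id] = node
        return node

    root = visit(tree)
    return SketchTree(root=root, params=tree_params, nodes=nodes)


def cluster_screen(screen: Screen, tree_params: TreeParams | None = None) -> SketchTree:
    """Distance matrix + linkage + sketch tree in one call."""
    tree_params = tree_params or TreeParams()
    D = sketch_distance_matrix(screen)
    return build_sketch_tree(screen, linkage_tree(D), tree_params)
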