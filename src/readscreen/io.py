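"""File formats: FASTA/FASTQ input, screen persistence, TSV reports.

The screen container is a versioned plain-text format (diffable and
language-neutral): a ``#``-prefixed key-value header, one ``>``-introduced
section per genome listing its stored hashes in decimal (with a weight or
position column where the method requires one), and an optional ``@tree``
block holding the clustering topology plus the hash set of every internal
node. Identity-hash screens are flagged in the header so they cannot be
mixed with production screens.
"""

from __future__ import annotations

import gzip
import io as _io
import os
from dataclasses import dataclass, field
from typing import Iterator, TextIO

import numpy as np
from Bio import SeqIO

from .classify import ClassificationResult
from .cluster import SketchTree, SketchTreeNode, TreeParams
from .screen import GenomeSketch, MethodParams, Screen, ScreenParams

FORMAT_VERSION = 1


class ScreenFormatError(ValueError):
    """Raised for malformed or incompatible screen containers."""


@dataclass
class ScreenContainer:
    """A screen plus its optional sketch tree and provenance, as persisted."""

    screen: Screen
    tree: SketchTree | None = None
    provenance: list[tuple[str, float]] = field(default_factory=list)
    format_version: int = FORMAT_VERSION


def _open_text(path: str | os.PathLike) -> TextIO:
    path = os.fspath(path)
    if path.endswith(".gz"):
        return _io.TextIOWrapper(gzip.open(path, "rb"), encoding="ascii")
    return open(path, encoding="ascii")


def read_fasta(path: str | os.PathLike) -> list[tuple[str, str]]:
    """Ordered (id, sequence) records from a FASTA file (optionally gzipped).

    The record id is the first whitespace-delimited token of the header and
    sequences are uppercased.
    """
    with _open_text(path) as fh:
        first = fh.readline()
        lineno = 1
        while first and not first.strip():
            first = fh.readline()
            lineno += 1
        if not first or not first.startswith(">"):
            raise ValueError(
                f"{path}: line {lineno}: expected a FASTA header starting with '>'"
            )
        fh.seek(0)
        return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(fh, "fasta")]


def read_reads(path: str | os.PathLike) -> Iterator[tuple[str, str]]:
    """Reads from FASTA or FASTQ (by extension), uppercased."""
    p = os.fspath(path)
    stem = p[:-3] if p.endswith(".gz") else p
    fmt = "fastq" if stem.endswith((".fastq", ".fq")) else "fasta"
    with _open_text(p) as fh:
        for rec in SeqIO.parse(fh, fmt):
            yield rec.id, str(rec.seq).upper()


def write_fasta(records: list[tuple[str, str]], path: str | os.PathLike, width: int = 80) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def provenance_for(paths: list[str | os.PathLike]) -> list[tuple[str, float]]:
    """Input filename + mtime pairs (deterministic across re-runs)."""
    return [(os.fspath(p), os.path.getmtime(p)) for p in paths]


def _write_sketch(fh: TextIO, sk: GenomeSketch, method: str) -> None:
    fh.write(f">{sk.genome_id}\t{sk.genome_size}\t{len(sk.hashes)}\n")
    if method == "weighted_minhash":
        assert sk.weights is not None
        for h, w in zip(sk.hashes, sk.weights):
            fh.write(f"{int(h)}\t{int(w)}\n")
    elif method in ("order_minhash", "minimizer") and sk.positions is not None:
        pos, hashes = sk.position_order()
        for p, h in zip(pos, hashes):
            fh.write(f"{int(h)}\t{int(p)}\n")
    else:
        for h in sk.hashes:
            fh.write(f"{int(h)}\n")


def _topology(node: SketchTreeNode) -> str:
    if node.is_leaf:
        return str(node.node_id)
    l, r = node.children
    return f"({_topology(l)},{_topology(r)}){node.node_id}"


def save_screen(container: ScreenContainer, path: str | os.PathLike) -> None:
    """Serialize a screen container to the versioned text format."""
    screen = container.screen
    p, m = screen.params, screen.method
    with open(path, "w") as fh:
        fh.write(f"#readscreen-screen\tv{container.format_version}\n")
        fh.write(f"#k\t{p.k}\n")
        fh.write(f"#read_length\t{p.read_length}\n")
        fh.write(f"#error_rate\t{p.error_rate!r}\n")
        fh.write(f"#target_matches\t{p.target_matches}\n")
        seed = "identity" if p.hash_seed is None else str(p.hash_seed)
        fh.write(f"#hash_seed\t{seed}\n")
        fh.write(f"#method\t{m.method}\n")
        if m.sublist_length is not None:
            fh.write(f"#sublist_length\t{m.sublist_length}\n")
        fh.write(f"#weight_multiplier\t{m.weight_multiplier}\n")
        fh.write(f"#window_multiplier\t{m.window_multiplier}\n")
        for name, mtime in container.provenance:
            fh.write(f"#input\t{name}\t{mtime!r}\n")
        for sk in screen.sketches:
            _write_sketch(fh, sk, m.method)
        if container.tree is not None:
            tp = container.tree.params
            fh.write(f"@tree\t{tp.downsample_mode}\t{tp.f!r}\t{tp.rng_seed}\n")
            fh.write(f"@topology\t{_topology(container.tree.root)}\n")
            for nid in sorted(container.tree.nodes):
                node = container.tree.nodes[nid]
                if node.is_leaf:
                    continue
                fh.write(f"@node\t{nid}\t{len(node.hashes)}\n")
                for h in node.hashes:
                    fh.write(f"{int(h)}\n")


def _parse_topology(s: str) -> tuple:
    """Parse '(l,r)id' nested topology into (id, left, right) tuples."""

    def parse(i: int) -> tuple[tuple | int, int]:
        if s[i] == "(":
            left, i = parse(i + 1)
            assert s[i] == ","
            right, i = parse(i + 1)
            assert s[i] == ")"
            i += 1
            j = i
            while j < len(s) and s[j].isdigit():
                j += 1
            return (int(s[i:j]), left, right), j
        j = i
        while j < len(s) and s[j].isdigit():
            j += 1
        return int(s[i:j]), j

    node, i = parse(0)
    if i != len(s):
        raise ScreenFormatError(f"trailing characters in topology: {s[i:]!r}")
    return node


def load_screen(path: str | os.PathLike) -> ScreenContainer:
    """Load a screen container; inverse of :func:`save_screen`."""
    header: dict[str, str] = {}
    provenance: list[tuple[str, float]] = []
    sketches: list[GenomeSketch] = []
    tree_spec = None
    topology = None
    node_hashes: dict[int, np.ndarray] = {}

    with _open_text(path) as fh:
        lines = fh.read().splitlines()
    if not lines or not lines[0].startswith("#readscreen-screen"):
        raise ScreenFormatError(f"{path}: not a readscreen screen container")
    version = lines[0].split("\t")[1]
    if version != f"v{FORMAT_VERSION}":
        raise ScreenFormatError(
            f"{path}: unsupported format version {version} (expected v{FORMAT_VERSION})"
        )

    cur: list[str] | None = None
    cur_meta: tuple[str, int] | None = None
    cur_node: int | None = None

    def flush() -> None:
        nonlocal cur, cur_meta, cur_node
        if cur is None:
            return
        if cur_meta is not None:
            gid, gsize = cur_meta
            method = header["method"]
            if method == "weighted_minhash":
                pairs = [ln.split("\t") for ln in cur]
                hashes = np.array([int(a) for a, _ in pairs], dtype=np.uint64)
                weights = np.array([int(b) for _, b in pairs], dtype=np.int64)
                sketches.append(GenomeSketch(gid, gsize, hashes, weights=weights))
            elif method in ("order_minhash", "minimizer") and cur and "\t" in cur[0]:
                pairs = [ln.split("\t") for ln in cur]
                h = np.array([int(a) for a, _ in pairs], dtype=np.uint64)
                pos = np.array([int(b) for _, b in pairs], dtype=np.int64)
                positions = np.column_stack([pos, h.view(np.int64)])
                sk = GenomeSketch(gid, gsize, np.sort(h), positions=positions)
                if method == "order_minhash":
                    L = int(header["sublist_length"])
                    n_lists = len(h) // L
                    sk.sublists = [
                        tuple(int(x) for x in h[i * L : (i + 1) * L])
                        for i in range(n_lists)
                    ]
                sketches.append(sk)
            else:
                hashes = np.array([int(ln) for ln in cur], dtype=np.uint64)
                sketches.append(GenomeSketch(gid, gsize, hashes))
        elif cur_node is not None:
            node_hashes[cur_node] = np.array([int(ln) for ln in cur], dtype=np.uint64)
        cur = cur_meta = cur_node = None

    for ln in lines[1:]:
        if not ln:
            continue
        if ln.startswith("#input"):
            _, name, mtime = ln.split("\t")
            provenance.append((name, float(mtime)))
        elif ln.startswith("#"):
            key, _, val = ln[1:].partition("\t")
            header[key] = val
        elif ln.startswith(">"):
            flush()
            parts = ln[1:].split("\t")
            cur_meta = (parts[0], int(parts[1]))
            cur = []
        elif ln.startswith("@tree"):
            flush()
            _, mode, f, seed = ln.split("\t")
            tree_spec = TreeParams(downsample_mode=mode, f=float(f), rng_seed=int(seed))
        elif ln.startswith("@topology"):
            topology = _parse_topology(ln.split("\t")[1])
        elif ln.startswith("@node"):
            flush()
            cur_node = int(ln.split("\t")[1])
            cur = []
        else:
            if cur is None:
                raise ScreenFormatError(f"{path}: stray data line {ln!r}")
            cur.append(ln)
    flush()

    seed_s = header["hash_seed"]
    params = ScreenParams(
        k=int(header["k"]),
        read_length=int(header["read_length"]),
        error_rate=float(header["error_rate"]),
        target_matches=int(header["target_matches"]),
        hash_seed=None if seed_s == "identity" else int(seed_s),
    )
    method = MethodParams(
        method=header["method"],
        sublist_length=(
            int(header["sublist_length"]) if "sublist_length" in header else None
        ),
        weight_multiplier=int(header.get("weight_multiplier", 1)),
        window_multiplier=int(header.get("window_multiplier", 2)),
    )
    screen = Screen(params=params, method=method, sketches=sketches)

    tree = None
    if tree_spec is not None and topology is not None:
        nodes: dict[int, SketchTreeNode] = {}

        def build(t) -> SketchTreeNode:
            if isinstance(t, int):
                sk = sketches[t]
                node = SketchTreeNode(
                    node_id=t, hashes=sk.hashes, genome_ids=(sk.genome_id,), height=0
                )
            else:
                nid, lt, rt = t
                left, right = build(lt), build(rt)
                node = SketchTreeNode(
                    node_id=nid,
                    children=(left, right),
                    hashes=node_hashes[nid],
                    genome_ids=left.genome_ids + right.genome_ids,
                    height=max(left.height, right.height) + 1,
                )
            nodes[node.node_id] = node
            return node

        tree = SketchTree(root=build(topology), params=tree_spec, nodes=nodes)

    return ScreenContainer(
        screen=screen, tree=tree, provenance=provenance, format_version=FORMAT_VERSION
    )


def check_compatible(screen: Screen, k: int | None, hash_seed: int | None | str = "unset") -> None:
    """Refuse to use a screen with mismatched k or hash seed."""
    if k is not None and k != screen.params.k:
        raise ScreenFormatError(
            f"screen was built with k={screen.params.k}, but k={k} was requested"
        )
    if hash_seed != "unset" and hash_seed != screen.params.hash_seed:
        raise ScreenFormatError(
            f"screen was built with hash_seed={screen.params.hash_seed}, "
            f"but hash_seed={hash_seed} was requested"
        )


def _fmt_predicted(pred: str | tuple[str, ...]) -> str:
    return ",".join(pred) if isinstance(pred, tuple) else pred


def write_report(
    results: list[ClassificationResult],
    path: str | os.PathLike,
    parameters: dict | None = None,
    metrics: dict | None = None,
) -> None:
    """Per-read TSV report with a ``#``-prefixed summary block.

    The summary echoes all supplied parameters and, when evaluation metrics
    are given, accuracy / unclassified / tie fractions and the per-genome
    accuracy table.
    """
    if not results:
        raise ValueError("cannot write a report for zero results")
    with open(path, "w") as fh:
        fh.write("#readscreen-report\tv1\n")
        for key, val in (parameters or {}).items():
            fh.write(f"#param\t{key}\t{val}\n")
        fh.write(f"#n_reads\t{len(results)}\n")
        if metrics:
            fh.write(f"#accuracy\t{metrics['accuracy']:.6f}\n")
            fh.write(f"#unclassified_fraction\t{metrics['unclassified_fraction']:.6f}\n")
            fh.write(f"#tie_fraction\t{metrics['tie_fraction']:.6f}\n")
            for g, acc in metrics["per_genome_accuracy"].items():
                c, n = metrics["per_genome_counts"][g]
                fh.write(f"#genome\t{g}\t{acc:.6f}\t{c}\t{n}\n")
        fh.write("read_id\tpredicted\tscore\tn_shared\ttied_with\tstatus\n")
        for r in results:
            fh.write(
                f"{r.read_id}\t{_fmt_predicted(r.predicted)}\t{r.score}\t"
                f"{r.n_shared}\t{','.join(r.tied_with)}\t{r.status}\n"
            )


def read_report(path: str | os.PathLike) -> list[ClassificationResult]:
    """Reconstruct per-read results from a report TSV (summary lines skipped)."""
    results = []
    with _open_text(path) as fh:
        for ln in fh:
            ln = ln.rstrip("\n")
            if not ln or ln.startswith("#") or ln.startswith("read_id\t"):
                continue
            rid, pred, score, n_shared, tied, status = ln.split("\t")
            predicted: str | tuple[str, ...] = pred
            if status == "tie_stopped":
                predicted = tuple(pred.split(","))
            results.append(
                ClassificationResult(
                    read_id=rid,
                    predicted=predicted,
                    score=int(score),
                    n_shared=int(n_shared),
                    tied_with=tied.split(",") if tied else [],
                    status=status,
                )
            )
    return results


def write_truth(reads, path: str | os.PathLike) -> None:
    """Sidecar ground-truth TSV for simulated reads."""
    with open(path, "w") as fh:
        fh.write("read_id\tgenome_id\tstart\tstrand\tn_errors\n")
        for r in reads:
            fh.write(f"{r.read_id}\t{r.true_genome}\t{r.start}\t{r.strand}\t{r.n_errors}\n")


def read_truth(path: str | os.PathLike) -> dict[str, str]:
    truth = {}
    with _open_text(path) as fh:
        for ln in fh:
            if ln.startswith("read_id\t") or not ln.strip():
                continue
            parts = ln.rstrip("\n").split("\t")
            truth[parts[0]] = parts[1]
    return truth
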