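"""Population reference trees from MinHash distances, and winner tracing.

A panel genome (assembly or read set) is summarised by a bottom-k MinHash
sketch of its canonical k-mers: k-mers below a multiplicity floor are dropped
(a read-error filter), the rest are hashed with a fixed 64-bit mixer, and the
``sketch_size`` smallest hash values are retained. Pairwise Jaccard indices
estimated from merged bottom sketches are converted to Mash distances

    d = -(1/k) * ln(2j / (1 + j)),

an estimate of the per-base mutation rate between two genomes, and the
distance matrix is clustered with UPGMA (average linkage, ultrametric output)
into the population reference tree. Per-sub-region top-scoring calls are then
traced onto the tree, annotating each leaf, internal node and lineage with the
number of times it was (an ancestor of) a winner.
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np

from .kmer import canonical_kmer_codes
from .similarity import Assignment, ASSIGNED, AMBIGUOUS

__all__ = [
    "Sketch",
    "PopulationTree",
    "TraceResult",
    "count_kmers",
    "minhash_sketch",
    "sketch_from_sequences",
    "sketch_jaccard",
    "mash_distance",
    "mash_distance_matrix",
    "upgma",
    "neighbor_joining",
    "trace",
    "write_sketch",
    "read_sketch",
    "read_lineage_map",
    "write_trace_tsv",
]

# Fixed hash seed so sketches are reproducible across runs and machines;
# recorded in every sketch file.
DEFAULT_HASH_SEED = 0x5EED_1D


def _hash64(codes: np.ndarray, seed: int = DEFAULT_HASH_SEED) -> np.ndarray:
    """Vectorised splitmix64 finalizer over packed k-mer codes (wraps mod 2^64)."""
    x = codes.astype(np.uint64) + np.uint64((seed * 0x9E3779B97F4A7C15) & 0xFFFFFFFFFFFFFFFF)
    x = (x ^ (x >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    x = (x ^ (x >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    return x ^ (x >> np.uint64(31))


@dataclass
class Sketch:
    """Bottom-k MinHash sketch of one sample's canonical k-mer content."""

    sample_id: str
    k: int
    sketch_size: int
    min_freq: int
    hashes: np.ndarray  # sorted ascending, <= sketch_size distinct uint64
    hash_seed: int = DEFAULT_HASH_SEED

    def __post_init__(self) -> None:
        self.hashes = np.asarray(self.hashes, dtype=np.uint64)


def count_kmers(sequences: Iterable[str], k: int) -> tuple[np.ndarray, np.ndarray]:
    """Canonical k-mer multiplicity table over all input sequences.

    Returns (codes, counts), codes sorted ascending. Reads should be passed
    individually so multiplicities reflect sequencing depth.
    """
    chunks = [canonical_kmer_codes(seq, k, unique=False) for seq in sequences]
    chunks = [c for c in chunks if c.size]
    if not chunks:
        return np.empty(0, np.uint64), np.empty(0, np.int64)
    codes, counts = np.unique(np.concatenate(chunks), return_counts=True)
    return codes, counts


def minhash_sketch(
    kmer_multiset: tuple[np.ndarray, np.ndarray] | Mapping[int, int],
    sketch_size: int = 1_000_000,
    min_freq: int = 2,
    *,
    k: int = 21,
    sample_id: str = "",
    hash_seed: int = DEFAULT_HASH_SEED,
) -> Sketch:
    """Sketch a k-mer multiplicity table.

    K-mers with multiplicity < ``min_freq`` are discarded (with reads as
    input this removes most error k-mers; for assemblies use ``min_freq=1``),
    the remainder hashed, and the ``sketch_size`` smallest distinct hashes
    kept.
    """
    if sketch_size < 1:
        raise ValueError("sketch_size must be >= 1")
    if isinstance(kmer_multiset, Mapping):
        codes = np.fromiter(kmer_multiset.keys(), dtype=np.uint64, count=len(kmer_multiset))
        counts = np.fromiter(kmer_multiset.values(), dtype=np.int64, count=len(kmer_multiset))
    else:
        codes, counts = kmer_multiset
    keep = np.asarray(counts) >= min_freq
    kept = np.asarray(codes, dtype=np.uint64)[keep]
    if kept.size == 0:
        warnings.warn(f"{sample_id or 'sample'}: no k-mers at multiplicity >= {min_freq}; empty sketch")
        return Sketch(sample_id, k, sketch_size, min_freq, np.empty(0, np.uint64), hash_seed)
    hashes = np.unique(_hash64(kept, hash_seed))[:sketch_size]
    return Sketch(sample_id, k, sketch_size, min_freq, hashes, hash_seed)


def sketch_from_sequences(
    sequences: Iterable[str],
    k: int = 21,
    sketch_size: int = 1_000_000,
    min_freq: int = 2,
    sample_id: str = "",
    hash_seed: int = DEFAULT_HASH_SEED,
) -> Sketch:
    """Convenience: count canonical k-mers over ``sequences`` and sketch them."""
    return minhash_sketch(
        count_kmers(sequences, k), sketch_size, min_freq, k=k, sample_id=sample_id, hash_seed=hash_seed
    )


def sketch_jaccard(a: Sketch, b: Sketch) -> float:
    """Jaccard index estimated from two bottom sketches (merged estimator).

    The smallest ``sketch_size`` distinct hashes of the union are taken as a
    pseudo-random sample of the union; the fraction of them present in both
    sketches estimates J(A, B). Exact whenever both inputs were smaller than
    the sketch size.
    """
    if a.k != b.k:
        raise ValueError(f"k mismatch: {a.k} vs {b.k}")
    if a.hash_seed != b.hash_seed:
        raise ValueError("sketches built with different hash seeds are not comparable")
    if a.hashes.size == 0 or b.hashes.size == 0:
        return 0.0
    union = np.union1d(a.hashes, b.hashes)
    s = min(min(a.sketch_size, b.sketch_size), union.size)
    bottom = union[:s]
    shared = np.intersect1d(a.hashes, b.hashes, assume_unique=True)
    n_shared = np.intersect1d(bottom, shared, assume_unique=True).size
    return n_shared / s


def mash_distance(j: float, k: int) -> float:
    """Mash distance d = -(1/k) ln(2j/(1+j)); 0 at j=1, capped at 1 as j -> 0."""
    if not 0.0 <= j <= 1.0:
        raise ValueError(f"jaccard estimate out of [0,1]: {j}")
    if j == 0.0:
        return 1.0
    d = -(1.0 / k) * math.log(2.0 * j / (1.0 + j))
    return min(max(d, 0.0), 1.0)


def mash_distance_matrix(sketches: Sequence[Sketch]) -> tuple[list[str], np.ndarray]:
    """All-vs-all Mash distances; returns (sample ids, symmetric matrix)."""
    labels = [s.sample_id for s in sketches]
    n = len(sketches)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = mash_distance(sketch_jaccard(sketches[i], sketches[j]), sketches[i].k)
            dist[i, j] = dist[j, i] = d
    return labels, dist


# ---------------------------------------------------------------------------
# trees


@dataclass
class PopulationTree:
    """Leaf-labelled tree with branch lengths and a leaf -> lineage map."""

    tree: dendropy.Tree
    lineage_map: dict[str, str] = field(default_factory=dict)

    @property
    def leaf_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    @classmethod
    def from_newick(cls, newick: str | Path, lineage_map: Mapping[str, str] | None = None) -> "PopulationTree":
        text = Path(newick).read_text() if isinstance(newick, Path) or (
            isinstance(newick, str) and "\n" not in newick and Path(newick).is_file()
        ) else str(newick)
        tree = dendropy.Tree.get(data=text, schema="newick")
        return cls(tree, dict(lineage_map or {}))

    def to_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()


def upgma(dist: np.ndarray, labels: Sequence[str]) -> PopulationTree:
    """Average-linkage (UPGMA) agglomerative clustering of a distance matrix.

    Produces an ultrametric tree: a merge at distance d places the new node at
    height d/2, each child branch spanning down to the child's own height.
    Equal-distance merges are broken by the lexicographically smallest pair of
    cluster representatives, so output is deterministic.
    """
    dist = np.asarray(dist, dtype=float)
    n = len(labels)
    if dist.shape != (n, n):
        raise ValueError(f"distance matrix shape {dist.shape} does not match {n} labels")
    if not np.allclose(dist, dist.T) or not np.allclose(np.diag(dist), 0.0):
        raise ValueError("distance matrix must be symmetric with a zero diagonal")
    if n == 0:
        raise ValueError("no taxa")

    # cluster -> (newick fragment, height, size, representative label)
    clusters: dict[int, tuple[str, float, int, str]] = {
        i: (str(labels[i]), 0.0, 1, str(labels[i])) for i in range(n)
    }
    d = {(i, j): dist[i, j] for i in range(n) for j in range(i + 1, n)}
    next_id = n
    while len(clusters) > 1:
        keys = sorted(clusters)
        best = None
        for ai in range(len(keys)):
            for bi in range(ai + 1, len(keys)):
                i, j = keys[ai], keys[bi]
                dij = d[(min(i, j), max(i, j))]
                pair_names = tuple(sorted((clusters[i][3], clusters[j][3])))
                cand = (dij, pair_names, i, j)
                if best is None or cand < best:
                    best = cand
        dij, _, i, j = best
        ni, nj = clusters[i], clusters[j]
        if nj[3] < ni[3]:  # children ordered by smallest leaf label
            ni, nj = nj, ni
        height = dij / 2.0
        frag = f"({ni[0]}:{height - ni[1]:.10g},{nj[0]}:{height - nj[1]:.10g})"
        size = ni[2] + nj[2]
        rep = min(ni[3], nj[3])
        # average-linkage update
        for m in list(clusters):
            if m in (i, j):
                continue
            dim = d[(min(i, m), max(i, m))]
            djm = d[(min(j, m), max(j, m))]
            d[(min(next_id, m), max(next_id, m))] = (ni[2] * dim + nj[2] * djm) / size
        del clusters[i], clusters[j]
        clusters[next_id] = (frag, height, size, rep)
        next_id += 1
    frag, height, _, _ = next(iter(clusters.values()))
    newick = frag + ";" if frag.startswith("(") else f"({frag}:0);"
    tree = dendropy.Tree.get(data=newick, schema="newick")
    return PopulationTree(tree)


def neighbor_joining(dist: np.ndarray, labels: Sequence[str]) -> PopulationTree:
    """Neighbor-joining alternative (non-ultrametric), via dendropy."""
    buf = io.StringIO()
    buf.write("," + ",".join(str(l) for l in labels) + "\n")
    for i, lab in enumerate(labels):
        buf.write(str(lab) + "," + ",".join(f"{v:.10g}" for v in dist[i]) + "\n")
    buf.seek(0)
    pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(buf, delimiter=",")
    return PopulationTree(pdm.nj_tree())


# ---------------------------------------------------------------------------
# tracing


@dataclass
class TraceResult:
    """Aggregated per-sub-region winners over a population tree.

    ``N`` counts every (region, winning sample) pair once, so tied winners of
    one region each contribute 1.
    """

    leaf_counts: dict[str, int]
    node_counts: dict[str, int]  # internal nodes, preorder ids n0, n1, ...
    lineage_counts: dict[str, int]
    N: int
    unassigned: dict[str, int] = field(default_factory=dict)  # status -> regions

    def leaf_fractions(self) -> dict[str, float]:
        return {s: c / self.N if self.N else 0.0 for s, c in self.leaf_counts.items()}

    def lineage_fractions(self) -> dict[str, float]:
        return {s: c / self.N if self.N else 0.0 for s, c in self.lineage_counts.items()}


def trace(assignments: Sequence[Assignment], tree: PopulationTree) -> TraceResult:
    """Aggregate top-scoring calls onto the population tree.

    Every assignment with status assigned/ambiguous_lineage increments the
    count of each of its winning leaves; internal-node counts are descendant
    sums; lineage counts follow the tree's leaf -> lineage map. Low-similarity
    and missing regions are tallied separately in ``unassigned``.
    """
    leaf_counts = {label: 0 for label in tree.leaf_labels}
    unassigned: dict[str, int] = {}
    for a in assignments:
        if a.status in (ASSIGNED, AMBIGUOUS):
            for s in a.top_samples:
                if s not in leaf_counts:
                    raise ValueError(f"winning sample {s!r} is not a leaf of the population tree")
                leaf_counts[s] += 1
        else:
            unassigned[a.status] = unassigned.get(a.status, 0) + 1
    total = sum(leaf_counts.values())

    node_counts: dict[str, int] = {}
    idx = 0
    for node in tree.tree.preorder_node_iter():
        if node.is_leaf():
            continue
        label = f"n{idx}"
        idx += 1
        node.label = label
        node_counts[label] = sum(
            leaf_counts[leaf.taxon.label] for leaf in node.leaf_iter()
        )
    lineage_counts: dict[str, int] = {}
    for leaf, count in leaf_counts.items():
        lineage = tree.lineage_map.get(leaf, "unassigned_lineage")
        lineage_counts[lineage] = lineage_counts.get(lineage, 0) + count
    return TraceResult(leaf_counts, node_counts, lineage_counts, total, unassigned)


def unrecovered_clades(reference: PopulationTree, estimate: PopulationTree) -> int:
    """Robinson–Foulds-style count of reference clades absent from the estimate.

    Counts bipartitions of the reference tree that the estimated tree does not
    contain (dendropy "false negatives"). For a polytomous reference — e.g. a
    star-within-star generating tree whose within-lineage structure is
    deliberately unresolved — this is the meaningful half of the symmetric
    difference: 0 means every resolved reference clade (every lineage) is
    recovered, while extra resolution in a binary estimate is not penalised.
    For two fully resolved trees on the same leaves, 0 in both directions is
    ordinary RF = 0.
    """
    from dendropy.calculate import treecompare

    tns = dendropy.TaxonNamespace()
    t_ref = dendropy.Tree.get(data=reference.to_newick(), schema="newick", taxon_namespace=tns)
    t_est = dendropy.Tree.get(data=estimate.to_newick(), schema="newick", taxon_namespace=tns)
    t_ref.encode_bipartitions()
    t_est.encode_bipartitions()
    _, fn = treecompare.false_positives_and_negatives(t_ref, t_est)
    return int(fn)


def annotated_newick(tree: PopulationTree, result: TraceResult) -> str:
    """Newick with winner counts as node comments (edge thickness source)."""
    clone = tree.tree.clone(depth=1)
    for node in clone.preorder_node_iter():
        if node.is_leaf():
            count = result.leaf_counts.get(node.taxon.label, 0)
        else:
            count = result.node_counts.get(node.label, 0)
        node.annotations.add_new("count", count)
    return clone.as_string(schema="newick", suppress_rooting=True, suppress_annotations=False).strip()


# ---------------------------------------------------------------------------
# plain-text round-tripping


def write_sketch(sketch: Sketch, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            f"#sample={sketch.sample_id}\tk={sketch.k}\tsketch_size={sketch.sketch_size}"
            f"\tmin_freq={sketch.min_freq}\thash_seed={sketch.hash_seed}\n"
        )
        for h in sketch.hashes:
            fh.write(f"{int(h)}\n")


def read_sketch(path: str | Path) -> Sketch:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#sample="):
            raise ValueError(f"{path}: not a sketch file")
        fields = dict(f.split("=", 1) for f in header[1:].rstrip("\n").split("\t"))
        hashes = np.array([int(line) for line in fh if line.strip()], dtype=np.uint64)
    return Sketch(
        sample_id=fields["sample"],
        k=int(fields["k"]),
        sketch_size=int(fields["sketch_size"]),
        min_freq=int(fields["min_freq"]),
        hashes=hashes,
        hash_seed=int(fields["hash_seed"]),
    )


def read_lineage_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV (sample, lineage)."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns (sample, lineage)")
            out[fields[0]] = fields[1]
    return out


def write_trace_tsv(result: TraceResult, path: str | Path, header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            for line in header.rstrip("\n").split("\n"):
                fh.write(f"#{line}\n")
        fh.write(f"#N={result.N}\tunassigned={result.unassigned}\n")
        fh.write("kind\tname\tcount\tfraction_of_N\n")
        for name, count in sorted(result.leaf_counts.items()):
            fh.write(f"leaf\t{name}\t{count}\t{count / result.N if result.N else 0:.6f}\n")
        for name, count in sorted(result.node_counts.items()):
            fh.write(f"node\t{name}\t{count}\t{count / result.N if result.N else 0:.6f}\n")
        for name, count in sorted(result.lineage_counts.items()):
            fh.write(f"lineage\t{name}\t{count}\t{count / result.N if result.N else 0:.6f}\n")
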