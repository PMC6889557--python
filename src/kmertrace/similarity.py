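"""Per-sample sub-region k-mer sets, similarity scoring and top-sample calls.

For every panel sample, k-mer sets are built per sub-region — either from read
alignments (aligned blocks projected onto reference coordinates, so every
sample is compared over exactly the same intervals) or directly from a genome
sequence colinear with the reference. The reference's own sub-region sets are
scored against each sample's sets, giving a region x sample similarity matrix
in [0, 1]; per region, the top-scoring sample(s) are called, subject to a
minimum-similarity floor and a lineage-ambiguity check.
"""

from __future__ import annotations

import math
import warnings
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .kmer import KmerSet, canonical_kmer_codes, containment, jaccard, read_fasta
from .partition import SubRegion

__all__ = [
    "SampleRegionSets",
    "SimilarityMatrix",
    "Assignment",
    "region_sets_from_alignments",
    "region_sets_from_genome",
    "reference_region_sets",
    "score_matrix",
    "assign_top",
    "write_matrix_tsv",
    "read_matrix_tsv",
    "write_assignments_tsv",
    "write_region_sets",
    "read_region_sets",
]

# statuses for matrix cells / region assignments
SCORED = "scored"
MISSING = "missing"
ASSIGNED = "assigned"
AMBIGUOUS = "ambiguous_lineage"
LOW_SIMILARITY = "low_similarity"

# CIGAR ops that consume reference/query (pysam numeric codes)
_CONSUMES_BOTH = {0, 7, 8}  # M, =, X
_CONSUMES_QUERY = {1, 4}  # I, S
_CONSUMES_REF = {2, 3}  # D, N


@dataclass
class SampleRegionSets:
    """Sub-region k-mer sets for one sample, keyed by SubRegion id."""

    sample_id: str
    k: int
    sets: dict[str, KmerSet] = field(default_factory=dict)
    read_support: dict[str, int] = field(default_factory=dict)
    skipped_records: int = 0  # alignments on contigs absent from the partition


class _RegionIndex:
    """Per-contig sorted interval lookup over a tiling partition."""

    def __init__(self, regions: Sequence[SubRegion]):
        self.by_contig: dict[str, tuple[list[int], list[int], list[str]]] = {}
        for r in regions:
            starts, ends, ids = self.by_contig.setdefault(r.contig, ([], [], []))
            starts.append(r.start)
            ends.append(r.end)
            ids.append(r.id)

    def overlapping(self, contig: str, start: int, end: int):
        """Yield (region_id, ovl_start, ovl_end) for regions hitting [start, end)."""
        entry = self.by_contig.get(contig)
        if entry is None:
            return
        starts, ends, ids = entry
        i = max(bisect_right(starts, start) - 1, 0)
        while i < len(starts) and starts[i] < end:
            a, b = max(starts[i], start), min(ends[i], end)
            if a < b:
                yield ids[i], a, b
            i += 1


def _aligned_blocks(record):
    """(ref_start, ref_end, query_start) for each match/mismatch CIGAR run."""
    rpos = record.reference_start
    qpos = 0
    for op, length in record.cigartuples or []:
        if op in _CONSUMES_BOTH:
            yield rpos, rpos + length, qpos
            rpos += length
            qpos += length
        elif op in _CONSUMES_QUERY:
            qpos += length
        elif op in _CONSUMES_REF:
            rpos += length
        # H, P consume neither


def region_sets_from_alignments(
    alignments,
    regions: Sequence[SubRegion],
    k: int,
    sample_id: str = "",
) -> SampleRegionSets:
    """Build per-region canonical k-mer sets from read alignments.

    ``alignments`` is a SAM/BAM path, an open ``pysam.AlignmentFile`` or an
    iterable of ``pysam.AlignedSegment``. For each aligned (match/mismatch)
    block of each primary mapped read, the read substring whose projected
    reference positions fall inside a sub-region contributes its canonical
    k-mers to that region's set; k-mers spanning an indel or a region boundary
    are not generated. Unmapped, secondary and supplementary records are
    ignored; records on contigs absent from the partition are counted in
    ``skipped_records``.
    """
    import pysam

    close = False
    if isinstance(alignments, (str, Path)):
        alignments = pysam.AlignmentFile(str(alignments), "r", check_sq=False)
        close = True
    index = _RegionIndex(regions)
    raw_sets: dict[str, set[int]] = {}
    support: dict[str, int] = {}
    skipped = 0
    try:
        for rec in alignments:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            contig = rec.reference_name
            if contig not in index.by_contig:
                skipped += 1
                continue
            seq = rec.query_sequence
            if not seq:
                continue
            for rstart, rend, qstart in _aligned_blocks(rec):
                for rid, a, b in index.overlapping(contig, rstart, rend):
                    support[rid] = support.get(rid, 0) + (b - a)
                    if b - a < k:
                        continue
                    sub = seq[qstart + (a - rstart) : qstart + (b - rstart)]
                    codes = canonical_kmer_codes(sub, k)
                    if codes.size:
                        raw_sets.setdefault(rid, set()).update(codes.tolist())
    finally:
        if close:
            alignments.close()
    if skipped:
        warnings.warn(f"{sample_id or 'sample'}: {skipped} alignment(s) on contigs absent from the partition")
    out = SampleRegionSets(sample_id=sample_id, k=k, read_support=support, skipped_records=skipped)
    for rid, codes in raw_sets.items():
        out.sets[rid] = KmerSet(k=k, members=np.fromiter(codes, dtype=np.uint64, count=len(codes)), source_id=f"{sample_id}|{rid}")
        out.sets[rid].members.sort()
    return out


def region_sets_from_genome(
    genome: Mapping[str, str] | str | Path,
    regions: Sequence[SubRegion],
    k: int,
    sample_id: str = "",
) -> SampleRegionSets:
    """Per-region k-mer sets from a genome colinear with the reference.

    Exact for the reference genome itself; for any other genome this is only
    meaningful when its coordinates are colinear with the reference (true for
    the substitution-only synthetic genomes; real diverged genomes should go
    through read alignments instead).
    """
    if isinstance(genome, (str, Path)):
        genome = read_fasta(genome)
    out = SampleRegionSets(sample_id=sample_id, k=k)
    for r in regions:
        seq = genome.get(r.contig)
        if seq is None:
            raise KeyError(f"region {r.id}: contig {r.contig!r} not in genome")
        if r.end > len(seq):
            raise ValueError(f"region {r.id} extends past contig end ({len(seq)})")
        out.sets[r.id] = KmerSet.from_sequence(seq[r.start : r.end], k, source_id=f"{sample_id}|{r.id}")
        out.read_support[r.id] = len(r)
    return out


def reference_region_sets(
    genome: Mapping[str, str] | str | Path, regions: Sequence[SubRegion], k: int
) -> dict[str, KmerSet]:
    """Reference sub-region sets keyed by region id (ordered as ``regions``)."""
    sample = region_sets_from_genome(genome, regions, k, sample_id="reference")
    return {r.id: sample.sets[r.id] for r in regions}


@dataclass
class SimilarityMatrix:
    """Sub-region x sample similarity scores in [0, 1].

    ``scores[i, j]`` is NaN where status is "missing" (no k-mers for the
    region in either the reference or the sample).
    """

    region_ids: list[str]
    sample_ids: list[str]
    scores: np.ndarray  # float, NaN == missing
    metric: str = "containment"

    def status(self, i: int, j: int) -> str:
        return MISSING if math.isnan(self.scores[i, j]) else SCORED

    def row(self, region_id: str) -> np.ndarray:
        return self.scores[self.region_ids.index(region_id)]


def score_matrix(
    ref_sets: Mapping[str, KmerSet],
    panel: Sequence[SampleRegionSets],
    metric: str = "containment",
) -> SimilarityMatrix:
    """Score every reference sub-region set against every panel sample.

    ``metric`` is "containment" (default; robust to unequal depth) or
    "jaccard". Cells where the sample has no k-mers for the region — or the
    reference set itself is empty — get status missing (NaN).
    """
    if not panel:
        raise ValueError("empty panel")
    ks = {s.k for s in panel} | {s.k for s in ref_sets.values()}
    if len(ks) > 1:
        raise ValueError(f"inconsistent k across inputs: {sorted(ks)}")
    score_fn = {"containment": containment, "jaccard": jaccard}.get(metric)
    if score_fn is None:
        raise ValueError(f"unknown metric {metric!r}")
    region_ids = list(ref_sets)
    sample_ids = [s.sample_id for s in panel]
    scores = np.full((len(region_ids), len(sample_ids)), np.nan)
    for i, rid in enumerate(region_ids):
        ref = ref_sets[rid]
        if len(ref) == 0:
            continue
        for j, sample in enumerate(panel):
            target = sample.sets.get(rid)
            if target is None or len(target) == 0:
                continue
            scores[i, j] = score_fn(ref, target)
    return SimilarityMatrix(region_ids, sample_ids, scores, metric=metric)


@dataclass
class Assignment:
    """Top-scoring call for one sub-region."""

    region_id: str
    status: str  # assigned | ambiguous_lineage | low_similarity | missing
    max_score: float  # NaN when status == missing
    top_samples: frozenset[str] = frozenset()
    lineages: frozenset[str] = frozenset()


def assign_top(
    matrix: SimilarityMatrix,
    lineage_map: Mapping[str, str],
    min_similarity: float = 0.75,
    tie_delta: float = 0.0,
) -> list[Assignment]:
    """Call the top-scoring sample(s) for every sub-region.

    All samples within ``tie_delta`` of the maximum count as tied winners.
    Regions whose maximum falls below ``min_similarity`` are flagged
    low_similarity (no winners); winners spanning more than one lineage are
    flagged ambiguous_lineage.
    """
    missing_lineage = [s for s in matrix.sample_ids if s not in lineage_map]
    if missing_lineage:
        raise KeyError(f"samples without a lineage: {missing_lineage}")
    out: list[Assignment] = []
    samples = np.asarray(matrix.sample_ids)
    for i, rid in enumerate(matrix.region_ids):
        row = matrix.scores[i]
        scored = ~np.isnan(row)
        if not scored.any():
            out.append(Assignment(rid, MISSING, float("nan")))
            continue
        max_score = float(np.nanmax(row))
        if max_score < min_similarity:
            out.append(Assignment(rid, LOW_SIMILARITY, max_score))
            continue
        winners = frozenset(map(str, samples[scored & (row >= max_score - tie_delta)]))
        lineages = frozenset(lineage_map[s] for s in winners)
        status = AMBIGUOUS if len(lineages) > 1 else ASSIGNED
        out.append(Assignment(rid, status, max_score, winners, lineages))
    return out


# ---------------------------------------------------------------------------
# plain-text round-tripping


def write_matrix_tsv(matrix: SimilarityMatrix, path: str | Path, header: str | None = None) -> None:
    """TSV: region id, then one score column per sample ("NA" for missing)."""
    with open(path, "w") as fh:
        if header:
            for line in header.rstrip("\n").split("\n"):
                fh.write(f"#{line}\n")
        fh.write("region\t" + "\t".join(matrix.sample_ids) + "\n")
        for i, rid in enumerate(matrix.region_ids):
            cells = ["NA" if math.isnan(v) else f"{v:.6f}" for v in matrix.scores[i]]
            fh.write(rid + "\t" + "\t".join(cells) + "\n")


def read_matrix_tsv(path: str | Path) -> SimilarityMatrix:
    region_ids: list[str] = []
    rows: list[list[float]] = []
    with open(path) as fh:
        sample_ids: list[str] | None = None
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if sample_ids is None:
                sample_ids = fields[1:]
                continue
            region_ids.append(fields[0])
            rows.append([float("nan") if v == "NA" else float(v) for v in fields[1:]])
    if sample_ids is None:
        raise ValueError(f"{path}: empty matrix file")
    return SimilarityMatrix(region_ids, sample_ids, np.asarray(rows, dtype=float))


def write_assignments_tsv(assignments: Sequence[Assignment], path: str | Path, header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            for line in header.rstrip("\n").split("\n"):
                fh.write(f"#{line}\n")
        fh.write("region\tstatus\tmax_score\ttop_samples\tlineages\n")
        for a in assignments:
            score = "NA" if math.isnan(a.max_score) else f"{a.max_score:.6f}"
            fh.write(
                f"{a.region_id}\t{a.status}\t{score}\t"
                f"{','.join(sorted(a.top_samples)) or '-'}\t{','.join(sorted(a.lineages)) or '-'}\n"
            )


def write_region_sets(sample: SampleRegionSets, path: str | Path) -> None:
    """One file per sample: blocks of ``>region_id`` followed by its k-mers."""
    from .kmer import decode_kmer

    with open(path, "w") as fh:
        fh.write(f"#sample={sample.sample_id}\tk={sample.k}\tregions={len(sample.sets)}\n")
        for rid, ks in sample.sets.items():
            fh.write(f">{rid}\tsupport={sample.read_support.get(rid, 0)}\n")
            for code in ks.members:
                fh.write(decode_kmer(int(code), ks.k) + "\n")


def read_region_sets(path: str | Path) -> SampleRegionSets:
    from .kmer import KmerSet, canonical_kmer_codes

    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#sample="):
            raise ValueError(f"{path}: not a region-sets file")
        fields = dict(f.split("=", 1) for f in header[1:].rstrip("\n").split("\t"))
        out = SampleRegionSets(sample_id=fields["sample"], k=int(fields["k"]))
        rid: str | None = None
        codes: list[int] = []

        def flush() -> None:
            if rid is not None:
                arr = np.unique(np.asarray(codes, dtype=np.uint64)) if codes else np.empty(0, np.uint64)
                out.sets[rid] = KmerSet(k=out.k, members=arr, source_id=f"{out.sample_id}|{rid}")

        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                flush()
                name, *attrs = line[1:].split("\t")
                rid = name
                codes = []
                for attr in attrs:
                    key, _, val = attr.partition("=")
                    if key == "support":
                        out.read_support[rid] = int(val)
            else:
                codes.append(int(canonical_kmer_codes(line, out.k)[0]))
        flush()
    return out
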