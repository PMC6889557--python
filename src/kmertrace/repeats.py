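"""Tandem-repeat unit alignment, clustering and copy-number estimation.

Flocculin (FLO) genes carry intragenic tandem repeats whose copy number
correlates with flocculation strength. Given known repeat unit sequences,
each unit is aligned locally against a gene (both strands); hits covering at
least half of the unit are chained into clusters wherever the gap between
consecutive hits is at most three unit lengths, and the copy number of a
cluster is its genomic span divided by the unit length — fractional values
are expected, since units decay at repeat-array edges.

Alignment is an internal Smith-Waterman-style local aligner (match +1,
mismatch -1, gap -2) with iterative masking of the best hit, so that every
repeat copy along the gene is enumerated.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from Bio import Align

from .kmer import read_fasta, reverse_complement

__all__ = [
    "RepeatUnit",
    "RepeatAlignment",
    "RepeatCluster",
    "align_units",
    "cluster_repeats",
    "repeat_report",
]


@dataclass(frozen=True)
class RepeatUnit:
    """One tandem repeat unit (e.g. the 135-nt unit A of FLO1)."""

    unit_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"repeat unit {self.unit_id!r} has empty sequence")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class RepeatAlignment:
    """A local alignment of a repeat unit against a gene (0-based half-open)."""

    unit_id: str
    gene_id: str
    start: int
    end: int
    unit_coverage: float  # aligned fraction of the unit, in [0, 1]
    identity: float  # matches / alignment columns, in [0, 1]
    strand: str = "+"
    score: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid hit interval [{self.start}, {self.end})")


@dataclass(frozen=True)
class RepeatCluster:
    """A chained run of repeat-unit hits along a gene."""

    unit_id: str
    gene_id: str
    span_start: int
    span_end: int
    copies: float  # (span_end - span_start) / unit length
    n_hits: int


def _make_aligner(match: float = 1.0, mismatch: float = -1.0, gap: float = -2.0) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    return aligner


def _best_hit(aligner, gene: str, unit_seq: str):
    """Best local alignment -> (score, gene_span, unit_span, matches, columns)."""
    alignments = aligner.align(gene, unit_seq)
    if len(alignments) == 0 or alignments.score <= 0:
        return None
    aln = alignments[0]
    gene_blocks, unit_blocks = aln.aligned
    gstart, gend = int(gene_blocks[0][0]), int(gene_blocks[-1][1])
    ustart, uend = int(unit_blocks[0][0]), int(unit_blocks[-1][1])
    matches = 0
    aligned_cols = 0
    for (ga, gb), (ua, ub) in zip(gene_blocks, unit_blocks):
        aligned_cols += gb - ga
        matches += sum(1 for x, y in zip(gene[ga:gb], unit_seq[ua:ub]) if x == y)
    gap_cols = (gend - gstart - aligned_cols) + (uend - ustart - aligned_cols)
    columns = aligned_cols + gap_cols
    return float(aln.score), (gstart, gend), (ustart, uend), matches, columns


def align_units(
    gene: str,
    unit: RepeatUnit,
    min_identity: float = 0.7,
    gene_id: str = "",
    min_score: float | None = None,
) -> list[RepeatAlignment]:
    """All local alignments of a repeat unit against a gene, both strands.

    Hits are found greedily: the best-scoring local alignment (forward or
    reverse-complement unit) is recorded and masked out of the gene, and the
    search repeats until the score drops below ``min_score`` (default
    ``max(10, unit.length / 4)``, which rejects the short spurious matches
    expected between random sequences). Hits below ``min_identity`` are not
    reported. Output is sorted by gene start; hits cannot overlap because of
    the masking.
    """
    if not gene:
        raise ValueError("empty gene sequence")
    if min_score is None:
        min_score = max(10.0, unit.length / 4.0)
    aligner = _make_aligner()
    strands = {"+": unit.sequence.upper(), "-": reverse_complement(unit.sequence.upper())}
    masked = list(gene.upper())
    hits: list[RepeatAlignment] = []
    max_rounds = 4 * len(gene) // unit.length + 16
    for _ in range(max_rounds):
        best = None
        for strand, useq in strands.items():
            res = _best_hit(aligner, "".join(masked), useq)
            if res is not None and (best is None or res[0] > best[1][0]):
                best = (strand, res)
        if best is None:
            break
        strand, (score, (gstart, gend), (ustart, uend), matches, columns) = best
        if score < min_score:
            break
        identity = matches / columns if columns else 0.0
        coverage = (uend - ustart) / unit.length
        if identity >= min_identity:
            hits.append(
                RepeatAlignment(
                    unit_id=unit.unit_id,
                    gene_id=gene_id,
                    start=gstart,
                    end=gend,
                    unit_coverage=coverage,
                    identity=identity,
                    strand=strand,
                    score=score,
                )
            )
        # mask the hit span so the next round finds the next-best copy
        for i in range(gstart, gend):
            masked[i] = "#"
    hits.sort(key=lambda h: (h.start, h.end))
    return hits


def cluster_repeats(
    hits: Sequence[RepeatAlignment],
    unit: RepeatUnit,
    min_cov: float = 0.5,
    gap_factor: float = 3.0,
) -> list[RepeatCluster]:
    """Chain unit hits into repeat clusters and estimate copy numbers.

    Hits covering less than ``min_cov`` of the unit are discarded; surviving
    hits (sorted by start) are chained while the gap between consecutive hits
    is at most ``gap_factor`` times the unit length — a strictly larger gap
    starts a new cluster. Cluster copy number = span / unit length.
    """
    kept = sorted((h for h in hits if h.unit_coverage >= min_cov), key=lambda h: (h.start, h.end))
    clusters: list[RepeatCluster] = []
    if not kept:
        return clusters
    max_gap = gap_factor * unit.length

    def emit(chain: list[RepeatAlignment]) -> None:
        span_start, span_end = chain[0].start, max(h.end for h in chain)
        clusters.append(
            RepeatCluster(
                unit_id=unit.unit_id,
                gene_id=chain[0].gene_id,
                span_start=span_start,
                span_end=span_end,
                copies=(span_end - span_start) / unit.length,
                n_hits=len(chain),
            )
        )

    chain = [kept[0]]
    for hit in kept[1:]:
        gap = hit.start - max(h.end for h in chain)
        if gap <= max_gap:
            chain.append(hit)
        else:
            emit(chain)
            chain = [hit]
    emit(chain)
    return clusters


def repeat_report(
    genes: Mapping[str, str] | str | Path,
    units: Mapping[str, str] | Sequence[RepeatUnit] | str | Path,
    min_identity: float = 0.7,
    min_cov: float = 0.5,
    gap_factor: float = 3.0,
) -> pd.DataFrame:
    """Gene x unit copy-number table (largest cluster per cell).

    Rows are genes (with a gene-length column); one column per repeat unit
    holding the copy number of the largest cluster rounded to one decimal, or
    "-" when the unit forms no cluster in that gene.
    """
    if isinstance(genes, (str, Path)):
        genes = read_fasta(genes)
    if isinstance(units, (str, Path)):
        units = read_fasta(units)
    if isinstance(units, Mapping):
        unit_list = [RepeatUnit(uid, seq) for uid, seq in units.items()]
    else:
        unit_list = list(units)
    rows = []
    for gene_id, gene_seq in genes.items():
        row: dict[str, object] = {"gene": gene_id, "gene_size": len(gene_seq)}
        for unit in unit_list:
            hits = align_units(gene_seq, unit, min_identity=min_identity, gene_id=gene_id)
            clusters = cluster_repeats(hits, unit, min_cov=min_cov, gap_factor=gap_factor)
            if clusters:
                best = max(clusters, key=lambda c: c.copies)
                row[unit.unit_id] = round(best.copies, 1)
            else:
                row[unit.unit_id] = "-"
        rows.append(row)
    return pd.DataFrame(rows, columns=["gene", "gene_size"] + [u.unit_id for u in unit_list])
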