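"""Read-depth copy-number estimation and heterozygous-SNP filtering.

Chromosome copy numbers are inferred from relative read depth: per-base depth
is summarised as medians over non-overlapping 100-bp windows, each
chromosome's median window depth is compared to the chromosome with the
smallest median, and the ratio (times the baseline ploidy) is rounded to an
integer copy number. Gene-level deviations are tested with an uncorrected
Z-test of a gene's mean coverage against the mean and standard deviation of
the surrounding fixed-copy-number sub-region. Heterozygous SNP calls are
filtered for chromosome-end proximity, minor-allele frequency and depth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import norm

__all__ = [
    "CoverageTrack",
    "RegionStats",
    "HetSNP",
    "GeneDeviation",
    "window_medians",
    "chromosome_copy_number",
    "segment_fixed_copy_regions",
    "gene_copy_deviation",
    "filter_het_snps",
    "read_depth_tsv",
    "depth_from_sam",
    "write_copy_number_tsv",
    "write_bedgraph",
]


@dataclass
class CoverageTrack:
    """Median depth per non-overlapping window, per contig.

    Window i of contig c spans ``[i*w, min((i+1)*w, L))``; the trailing
    partial window is included.
    """

    w: int
    medians: dict[str, np.ndarray] = field(default_factory=dict)

    def window_bounds(self, contig: str, length: int | None = None):
        meds = self.medians[contig]
        for i in range(meds.size):
            start = i * self.w
            end = (i + 1) * self.w
            if length is not None:
                end = min(end, length)
            yield start, end


@dataclass
class RegionStats:
    """A contiguous chromosomal sub-region with fixed copy number."""

    contig: str
    start: int
    end: int
    mean: float
    sd: float
    copy_number: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("standard deviation must be >= 0")


@dataclass(frozen=True)
class HetSNP:
    """A heterozygous SNP call (1-based position, MAF folded to [0, 0.5])."""

    contig: str
    pos: int
    ref: str
    alt: str
    maf: float
    depth: int


@dataclass(frozen=True)
class GeneDeviation:
    z: float
    p: float
    deviating: bool
    testable: bool = True


def window_medians(depths: Mapping[str, np.ndarray], w: int = 100) -> CoverageTrack:
    """Median per-base depth over non-overlapping w-bp windows.

    Even-count medians are the mean of the two middle values (numpy
    convention); the trailing partial window is included.
    """
    if w < 1:
        raise ValueError("window size must be >= 1")
    track = CoverageTrack(w=w)
    for contig, depth in depths.items():
        depth = np.asarray(depth, dtype=float)
        n_full = depth.size // w
        meds = []
        if n_full:
            meds.append(np.median(depth[: n_full * w].reshape(n_full, w), axis=1))
        if depth.size % w:
            meds.append([np.median(depth[n_full * w :])])
        track.medians[contig] = np.concatenate(meds) if meds else np.empty(0)
    return track


def chromosome_copy_number(track: CoverageTrack, baseline_ploidy: int = 1) -> dict[str, int]:
    """Integer copy number per contig, relative to the lowest-coverage contig.

    The chromosome with the smallest positive median window depth is taken to
    carry ``baseline_ploidy`` copies; every other chromosome's copy number is
    its median depth divided by that baseline, rounded to an integer.
    """
    contig_medians = {c: float(np.median(m)) for c, m in track.medians.items() if m.size}
    positive = [m for m in contig_medians.values() if m > 0]
    if not positive:
        raise ValueError("no contig with positive median coverage")
    base = min(positive)
    return {
        c: max(0, math.floor(baseline_ploidy * m / base + 0.5)) for c, m in contig_medians.items()
    }


def segment_fixed_copy_regions(
    track: CoverageTrack, baseline_ploidy: int = 1, min_windows: int = 1
) -> list[RegionStats]:
    """Derive fixed-copy-number sub-regions by segmenting the window track.

    Each window gets an integer copy number (relative to the genome-wide
    baseline, as in :func:`chromosome_copy_number` but per window); runs of
    equal copy number become one region, summarised by the mean and standard
    deviation of its window medians. An alternative to supplying curated
    regions directly.
    """
    contig_medians = [float(np.median(m)) for m in track.medians.values() if m.size]
    positive = [m for m in contig_medians if m > 0]
    if not positive:
        raise ValueError("no contig with positive median coverage")
    base = min(positive)
    out: list[RegionStats] = []
    for contig, meds in track.medians.items():
        if not meds.size:
            continue
        cn = np.maximum(0, np.floor(baseline_ploidy * meds / base + 0.5).astype(int))
        run_start = 0
        for i in range(1, meds.size + 1):
            if i == meds.size or cn[i] != cn[run_start]:
                if i - run_start >= min_windows:
                    vals = meds[run_start:i]
                    out.append(
                        RegionStats(
                            contig=contig,
                            start=run_start * track.w,
                            end=i * track.w,
                            mean=float(vals.mean()),
                            sd=float(vals.std(ddof=0)),
                            copy_number=int(cn[run_start]),
                        )
                    )
                run_start = i
    return out


def gene_copy_deviation(gene_mean: float, region: RegionStats, alpha: float = 0.05) -> GeneDeviation:
    """Uncorrected two-sided Z-test of a gene's mean coverage vs its sub-region.

    z = (gene_mean - region.mean) / region.sd; p is the two-sided standard
    normal tail probability; the gene is flagged deviating when p < alpha.
    A region with zero standard deviation makes the gene untestable.
    """
    if region.sd <= 0:
        return GeneDeviation(z=float("nan"), p=float("nan"), deviating=False, testable=False)
    z = (gene_mean - region.mean) / region.sd
    p = 2.0 * norm.sf(abs(z))
    return GeneDeviation(z=z, p=float(p), deviating=bool(p < alpha))


def filter_het_snps(
    snps: Sequence[HetSNP],
    contig_lengths: Mapping[str, int],
    end_excl: int = 10_000,
    min_maf: float = 0.15,
    min_depth: int = 3,
) -> list[HetSNP]:
    """Retain SNPs away from chromosome ends with adequate MAF and depth.

    A SNP survives iff its (1-based) position lies strictly inside
    ``(end_excl, L - end_excl]``, its minor-allele frequency is >= min_maf and
    its depth is >= min_depth — thresholds phrased as "below X" are strict
    exclusions, so boundary values are kept.
    """
    out = []
    for snp in snps:
        length = contig_lengths.get(snp.contig)
        if length is None:
            raise KeyError(f"SNP on unknown contig {snp.contig!r}")
        if snp.pos <= end_excl or snp.pos > length - end_excl:
            continue
        if snp.maf < min_maf or snp.depth < min_depth:
            continue
        out.append(snp)
    return out


# ---------------------------------------------------------------------------
# input/output


def read_depth_tsv(path: str | Path, contig_lengths: Mapping[str, int] | None = None) -> dict[str, np.ndarray]:
    """Per-base depth from a (contig, 1-based pos, depth) TSV.

    Positions absent from the file get depth 0. Without ``contig_lengths``
    each contig's length is taken as its largest listed position.
    """
    raw: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns (contig, pos, depth)")
            raw.setdefault(fields[0], []).append((int(fields[1]), int(fields[2])))
    out: dict[str, np.ndarray] = {}
    for contig, pairs in raw.items():
        length = contig_lengths[contig] if contig_lengths else max(p for p, _ in pairs)
        depth = np.zeros(length, dtype=np.int64)
        pos, val = np.array(pairs).T
        depth[pos - 1] = val
        out[contig] = depth
    return out


def read_het_snps_tsv(path: str | Path) -> list[HetSNP]:
    """VCF-like TSV: contig, pos (1-based), ref, alt, maf, depth."""
    out: list[HetSNP] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 6:
                raise ValueError(f"{path}:{lineno}: expected 6 columns")
            out.append(HetSNP(f[0], int(f[1]), f[2], f[3], float(f[4]), int(f[5])))
    return out


def write_het_snps_tsv(snps: Sequence[HetSNP], path: str | Path, header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            for line in header.rstrip("\n").split("\n"):
                fh.write(f"#{line}\n")
        fh.write("#contig\tpos\tref\talt\tmaf\tdepth\n")
        for s in snps:
            fh.write(f"{s.contig}\t{s.pos}\t{s.ref}\t{s.alt}\t{s.maf:.4f}\t{s.depth}\n")


def depth_from_sam(path: str | Path, contig_lengths: Mapping[str, int] | None = None) -> dict[str, np.ndarray]:
    """Per-base depth from sequential scanning of a SAM/BAM file.

    Counts match/mismatch CIGAR blocks of primary mapped reads; no index
    required.
    """
    import pysam

    from .similarity import _aligned_blocks

    with pysam.AlignmentFile(str(path), "r", check_sq=False) as af:
        lengths = dict(contig_lengths) if contig_lengths else dict(zip(af.references, af.lengths))
        depth = {c: np.zeros(n, dtype=np.int64) for c, n in lengths.items()}
        for rec in af:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            arr = depth.get(rec.reference_name)
            if arr is None:
                continue
            for rstart, rend, _ in _aligned_blocks(rec):
                arr[rstart : min(rend, arr.size)] += 1
    return depth


def write_copy_number_tsv(copy_numbers: Mapping[str, int], path: str | Path, header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            for line in header.rstrip("\n").split("\n"):
                fh.write(f"#{line}\n")
        fh.write("#contig\tcopy_number\n")
        for contig, cn in copy_numbers.items():
            fh.write(f"{contig}\t{cn}\n")


def write_bedgraph(
    track: CoverageTrack,
    path: str | Path,
    contig_lengths: Mapping[str, int] | None = None,
    header: str | None = None,
) -> None:
    """Per-window median depth as BEDGRAPH (0-based half-open)."""
    with open(path, "w") as fh:
        if header:
            for line in header.rstrip("\n").split("\n"):
                fh.write(f"#{line}\n")
        for contig in track.medians:
            length = contig_lengths.get(contig) if contig_lengths else None
            for (start, end), med in zip(track.window_bounds(contig, length), track.medians[contig]):
                fh.write(f"{contig}\t{start}\t{end}\t{med:.6g}\n")
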