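"""Partition reference contigs into fixed-size, non-overlapping sub-regions.

Sub-regions are the atomic unit of similarity scoring: each contig is tiled
left to right with windows of ``region_size`` (default 2000 bp). A trailing
remainder window is kept if it is at least k long (so it yields at least one
k-mer), otherwise dropped. Coordinates are 0-based half-open throughout; BED
is the on-disk convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

__all__ = ["SubRegion", "partition_reference", "write_bed", "read_bed", "read_fai"]


@dataclass(frozen=True)
class SubRegion:
    """A half-open reference interval ``[start, end)`` on ``contig``."""

    contig: str
    start: int
    end: int
    subgenome: str | None = None  # e.g. parental origin of the contig

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid interval {self.contig}:{self.start}-{self.end}")

    @property
    def id(self) -> str:
        return f"{self.contig}:{self.start}-{self.end}"

    def __len__(self) -> int:
        return self.end - self.start


def partition_reference(
    contig_lengths: Mapping[str, int] | str | Path,
    region_size: int = 2000,
    k: int = 21,
) -> list[SubRegion]:
    """Tile every contig with non-overlapping windows of ``region_size``.

    ``contig_lengths`` may be a {contig: length} mapping or a path to a
    samtools ``.fai`` index. The trailing remainder window is retained only if
    its length is >= k; output order is (contig order, start).
    """
    if isinstance(contig_lengths, (str, Path)):
        contig_lengths = read_fai(contig_lengths)
    if region_size < k:
        raise ValueError(f"region_size ({region_size}) must be >= k ({k})")
    regions: list[SubRegion] = []
    for contig, length in contig_lengths.items():
        pos = 0
        while pos < length:
            end = min(pos + region_size, length)
            if end - pos >= k:
                regions.append(SubRegion(contig, pos, end))
            pos = end
    return regions


def read_fai(path: str | Path) -> dict[str, int]:
    """Contig lengths from a ``.fai``-style table (name, length, ...)."""
    lengths: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            lengths[fields[0]] = int(fields[1])
    return lengths


def write_bed(regions: list[SubRegion], path: str | Path, header: str | None = None) -> None:
    """BED3+1 (contig, start, end, id) with an optional 5th subgenome column."""
    with open(path, "w") as fh:
        if header:
            for line in header.rstrip("\n").split("\n"):
                fh.write(f"#{line}\n")
        for r in regions:
            fields = [r.contig, str(r.start), str(r.end), r.id]
            if r.subgenome is not None:
                fields.append(r.subgenome)
            fh.write("\t".join(fields) + "\n")


def read_bed(path: str | Path) -> list[SubRegion]:
    regions: list[SubRegion] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 BED columns")
            subgenome = fields[4] if len(fields) > 4 else None
            regions.append(SubRegion(fields[0], int(fields[1]), int(fields[2]), subgenome))
    return regions
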