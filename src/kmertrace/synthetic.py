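"""Synthetic strain panels, admixed queries, reads, depth tracks and repeat genes.

The generator emulates the study design every other module consumes: a panel
of strains with lineage structure (lineage founders diverged from a common
ancestor, strains diverged from their founders), an admixed query genome
copied segment-wise from chosen donor strains, sequencing reads emitted as
aligned SAM records at their true positions, aneuploid per-base depth tracks,
and tandem-repeat genes of known composition. Mutations are substitutions
only (all changes equiprobable), which keeps every genome colinear with the
ancestor so ground truth projects exactly onto reference coordinates.

All randomness flows through one seeded generator per operation; the seed is
recorded in the returned truth object.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "SimTruth",
    "simulate_panel",
    "simulate_admixed_query",
    "simulate_reads",
    "simulate_aneuploid_depth",
    "simulate_repeat_gene",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_ENC = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _ENC[_b] = _i


def _encode(seq: str) -> np.ndarray:
    codes = _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (codes < 0).any():
        raise ValueError("synthetic sequences must be over ACGT")
    return codes.astype(np.uint8)


def _decode(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def _mutate(codes: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each site independently with probability ``rate``."""
    out = codes.copy()
    if rate <= 0:
        return out
    hit = rng.random(codes.size) < rate
    n = int(hit.sum())
    if n:
        out[hit] = (out[hit] + rng.integers(1, 4, size=n, dtype=np.uint8)) % 4
    return out


@dataclass
class SimTruth:
    """Ground truth of a simulation run (JSON-serializable)."""

    seed: int
    tree_newick: str = ""
    lineage_map: dict[str, str] = field(default_factory=dict)
    within_div: float = 0.0
    between_div: float = 0.0
    segments: list[tuple[str, int, int, str]] = field(default_factory=list)
    extra_div: float = 0.0
    ploidies: dict[str, int] = field(default_factory=dict)
    repeat_layout: list[tuple[str, int, int]] = field(default_factory=list)

    def donor_of(self, contig: str, start: int, end: int) -> str | None:
        """Donor of a reference interval, or None if it straddles a breakpoint."""
        donors = {
            seg[3]
            for seg in self.segments
            if seg[0] == contig and not (end <= seg[1] or start >= seg[2])
        }
        return donors.pop() if len(donors) == 1 else None

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        with open(path) as fh:
            data = json.load(fh)
        data["segments"] = [tuple(s) for s in data.get("segments", [])]
        data["repeat_layout"] = [tuple(s) for s in data.get("repeat_layout", [])]
        return cls(**data)


def simulate_panel(
    n_lineages: int,
    strains_per_lineage: int,
    genome: Mapping[str, int] | Sequence[int],
    within_div: float = 0.003,
    between_div: float = 0.02,
    seed: int = 0,
) -> tuple[dict[str, str], dict[str, dict[str, str]], SimTruth]:
    """A strain panel with lineage structure.

    A random ancestor genome is drawn; each lineage founder accumulates
    ``between_div`` substitutions per site from the ancestor, and each strain
    ``within_div`` from its founder (independently, so two strains of one
    lineage differ at ~2 * within_div of sites). Returns
    (ancestor, {sample: genome}, truth); sample ids are ``L{i}S{j}``.
    """
    if n_lineages < 1 or strains_per_lineage < 1:
        raise ValueError("need at least one lineage and one strain per lineage")
    if isinstance(genome, Mapping):
        contig_lengths = dict(genome)
    else:
        contig_lengths = {f"chr{i + 1:02d}": int(l) for i, l in enumerate(genome)}
    rng = np.random.default_rng(seed)
    ancestor_codes = {c: rng.integers(0, 4, size=l, dtype=np.uint8) for c, l in contig_lengths.items()}
    genomes: dict[str, dict[str, str]] = {}
    lineage_map: dict[str, str] = {}
    clades = []
    for i in range(1, n_lineages + 1):
        lineage = f"L{i}"
        founder = {c: _mutate(codes, between_div, rng) for c, codes in ancestor_codes.items()}
        leaf_labels = []
        for j in range(1, strains_per_lineage + 1):
            sample = f"{lineage}S{j}"
            genomes[sample] = {c: _decode(_mutate(codes, within_div, rng)) for c, codes in founder.items()}
            lineage_map[sample] = lineage
            leaf_labels.append(f"{sample}:{within_div:g}")
        clades.append("(" + ",".join(leaf_labels) + f"):{between_div:g}")
    newick = "(" + ",".join(clades) + ");"
    ancestor = {c: _decode(codes) for c, codes in ancestor_codes.items()}
    truth = SimTruth(
        seed=seed,
        tree_newick=newick,
        lineage_map=lineage_map,
        within_div=within_div,
        between_div=between_div,
    )
    return ancestor, genomes, truth


def simulate_admixed_query(
    panel: Mapping[str, Mapping[str, str]],
    segments: Sequence[tuple[str, int, int, str]],
    extra_div: float = 0.0,
    seed: int = 0,
) -> tuple[dict[str, str], SimTruth]:
    """A mosaic query copying donor sequence per segment.

    ``segments`` are (contig, start, end, donor_id) and must tile each query
    contig without overlap; ``extra_div`` adds private substitutions on top of
    the copied sequence.
    """
    if not segments:
        raise ValueError("no segments given")
    rng = np.random.default_rng(seed)
    by_contig: dict[str, list[tuple[str, int, int, str]]] = {}
    for seg in segments:
        contig, start, end, donor = seg
        if donor not in panel:
            raise KeyError(f"donor {donor!r} is not a panel member")
        if not 0 <= start < end:
            raise ValueError(f"invalid segment {seg}")
        by_contig.setdefault(contig, []).append(seg)
    query: dict[str, str] = {}
    for contig, segs in by_contig.items():
        segs.sort(key=lambda s: s[1])
        pos = 0
        parts = []
        for _, start, end, donor in segs:
            if start != pos:
                raise ValueError(f"segments do not tile contig {contig!r} (gap/overlap at {start})")
            donor_seq = panel[donor][contig]
            if end > len(donor_seq):
                raise ValueError(f"segment end {end} past donor contig length {len(donor_seq)}")
            parts.append(donor_seq[start:end])
            pos = end
        if pos != len(panel[segs[0][3]][contig]):
            raise ValueError(f"segments do not cover contig {contig!r} to its end")
        seq = "".join(parts)
        if extra_div > 0:
            seq = _decode(_mutate(_encode(seq), extra_div, rng))
        query[contig] = seq
    truth = SimTruth(seed=seed, segments=[tuple(s) for s in segments], extra_div=extra_div)
    return query, truth


def simulate_reads(
    genome: Mapping[str, str],
    coverage: float = 30.0,
    read_len: int = 150,
    err: float = 0.002,
    seed: int = 0,
    out_sam: str | Path | None = None,
    sample_name: str = "sim",
) -> list[str] | None:
    """Uniform error-bearing reads emitted as aligned SAM records.

    Read count per contig is round(coverage * L / read_len); start positions
    are uniform, per-base substitution errors occur at rate ``err``, and each
    record carries its true position with a full-match CIGAR (alignment is by
    construction, not inference). Writes a SAM file when ``out_sam`` is given,
    otherwise returns the SAM lines.
    """
    rng = np.random.default_rng(seed)
    lines = ["@HD\tVN:1.6\tSO:coordinate"]
    for contig, seq in genome.items():
        lines.append(f"@SQ\tSN:{contig}\tLN:{len(seq)}")
    lines.append(f"@PG\tID:kmertrace-sim\tPN:kmertrace-sim\tDS:sample={sample_name}")
    serial = 0
    for contig, seq in genome.items():
        L = len(seq)
        if L < read_len:
            continue
        codes = _encode(seq)
        n_reads = int(round(coverage * L / read_len))
        starts = np.sort(rng.integers(0, L - read_len + 1, size=n_reads))
        err_mask = rng.random((n_reads, read_len)) < err if err > 0 else None
        for i in range(n_reads):
            s = int(starts[i])
            read = codes[s : s + read_len]
            if err_mask is not None and err_mask[i].any():
                read = read.copy()
                idx = np.nonzero(err_mask[i])[0]
                read[idx] = (read[idx] + rng.integers(1, 4, size=idx.size, dtype=np.uint8)) % 4
            serial += 1
            lines.append(
                f"{sample_name}.{serial}\t0\t{contig}\t{s + 1}\t60\t{read_len}M\t*\t0\t0\t{_decode(read)}\t*"
            )
    if out_sam is not None:
        Path(out_sam).write_text("\n".join(lines) + "\n")
        return None
    return lines


def simulate_aneuploid_depth(
    contig_lengths: Mapping[str, int],
    ploidies: Mapping[str, int],
    per_copy_depth: float = 30.0,
    seed: int = 0,
    out_tsv: str | Path | None = None,
) -> dict[str, np.ndarray]:
    """Per-base Poisson depth with mean ploidy * per_copy_depth per contig."""
    rng = np.random.default_rng(seed)
    depth: dict[str, np.ndarray] = {}
    for contig, length in contig_lengths.items():
        ploidy = ploidies.get(contig)
        if ploidy is None:
            raise KeyError(f"no ploidy given for contig {contig!r}")
        mean = ploidy * per_copy_depth
        depth[contig] = (
            rng.poisson(mean, size=length).astype(np.int64) if mean > 0 else np.zeros(length, np.int64)
        )
    if out_tsv is not None:
        with open(out_tsv, "w") as fh:
            for contig, arr in depth.items():
                for pos, v in enumerate(arr, 1):
                    fh.write(f"{contig}\t{pos}\t{v}\n")
    return depth


def simulate_repeat_gene(
    units: Mapping[str, str],
    layout: Sequence[tuple[str, int, int]],
    seed: int = 0,
) -> tuple[str, SimTruth]:
    """A gene built from tandem repeat blocks.

    ``layout`` is a list of (unit_id, copies, gap): each entry appends
    ``copies`` exact copies of the unit followed by ``gap`` random bases.
    Truth records the layout; with gap 0 between blocks of one unit the true
    copy number of the resulting cluster is the sum of copies.
    """
    rng = np.random.default_rng(seed)
    parts: list[str] = []
    for unit_id, copies, gap in layout:
        if unit_id not in units:
            raise KeyError(f"unknown repeat unit {unit_id!r}")
        parts.append(units[unit_id] * int(copies))
        if gap > 0:
            parts.append(_decode(rng.integers(0, 4, size=int(gap), dtype=np.uint8)))
    gene = "".join(parts)
    truth = SimTruth(seed=seed, repeat_layout=[tuple(l) for l in layout])
    return gene, truth
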