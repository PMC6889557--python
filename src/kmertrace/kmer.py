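"""Canonical k-mer sets and set-based sequence similarity.

A genomic interval (or a pile of reads covering it) is reduced to the set of
its canonical k-mers: each k-long window over {A,C,G,T} is represented by the
lexicographic minimum of itself and its reverse complement, which makes the
representation strand-invariant. K-mers are stored 2-bit packed in unsigned
64-bit integers (so k <= 31), and sets are kept as sorted unique arrays.

Similarity between two sets is measured either as *containment* — the fraction
of the reference set found in the target, robust to unequal sequencing depth —
or as the Jaccard index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np

__all__ = [
    "KmerSet",
    "canonical_kmers",
    "canonical_kmer_codes",
    "containment",
    "jaccard",
    "reverse_complement",
    "decode_kmer",
    "read_fasta",
    "write_kmer_set",
    "read_kmer_set",
]

MAX_K = 31  # 2 bits per base in a uint64

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")

# base -> 2-bit code; anything not ACGT (either case) maps to -1
_CODES = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _CODES[ord(_b)] = _i
    _CODES[ord(_b.lower())] = _i

_DECODE = np.frombuffer(b"ACGT", dtype=np.uint8)


def reverse_complement(sequence: str) -> str:
    """Reverse complement of a nucleotide string (case preserved)."""
    return sequence.translate(_COMPLEMENT)[::-1]


def encode_bases(sequence: str) -> np.ndarray:
    """Per-base 2-bit codes (int8); non-ACGT bases become -1."""
    raw = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    return _CODES[raw]


def decode_kmer(code: int, k: int) -> str:
    """Inverse of the 2-bit packing: integer code -> k-mer string."""
    out = bytearray(k)
    c = int(code)
    for i in range(k - 1, -1, -1):
        out[i] = _DECODE[c & 3]
        c >>= 2
    return out.decode("ascii")


def canonical_kmer_codes(sequence: str, k: int, *, unique: bool = True) -> np.ndarray:
    """Canonical k-mer codes of every valid window of ``sequence``.

    Windows containing a non-ACGT symbol are skipped. Returns a uint64 array;
    sorted and deduplicated when ``unique`` (the default), otherwise one code
    per window in sequence order (the multiset view, used for counting).
    """
    if not 1 <= k <= MAX_K:
        raise ValueError(f"k must be in [1, {MAX_K}], got {k}")
    n = len(sequence) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    codes = encode_bases(sequence)
    invalid = codes < 0
    c = np.where(invalid, 0, codes).astype(np.uint64)
    fwd = np.zeros(n, dtype=np.uint64)
    rev = np.zeros(n, dtype=np.uint64)
    three = np.uint64(3)
    for j in range(k):
        fwd += c[j : j + n] << np.uint64(2 * (k - 1 - j))
        rev += (three - c[j : j + n]) << np.uint64(2 * j)
    canon = np.minimum(fwd, rev)
    if invalid.any():
        cum = np.concatenate(([0], np.cumsum(invalid)))
        ok = (cum[k:] - cum[:-k]) == 0
        canon = canon[ok]
    if unique:
        return np.unique(canon)
    return canon


@dataclass
class KmerSet:
    """A set of distinct canonical k-mers from one sequence region or sample.

    ``members`` is a sorted, deduplicated uint64 array of 2-bit packed codes.
    """

    k: int
    members: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.uint64))
    source_id: str = ""

    def __post_init__(self) -> None:
        self.members = np.asarray(self.members, dtype=np.uint64)

    def __len__(self) -> int:
        return int(self.members.size)

    def __contains__(self, kmer: str) -> bool:
        codes = canonical_kmer_codes(kmer, self.k)
        if codes.size != 1:
            return False
        i = np.searchsorted(self.members, codes[0])
        return bool(i < self.members.size and self.members[i] == codes[0])

    def kmers(self) -> Iterator[str]:
        """Yield members as canonical k-mer strings (sorted by code)."""
        for code in self.members:
            yield decode_kmer(int(code), self.k)

    @classmethod
    def from_sequence(cls, sequence: str, k: int, source_id: str = "") -> "KmerSet":
        return cls(k=k, members=canonical_kmer_codes(sequence, k), source_id=source_id)

    @classmethod
    def from_kmers(cls, kmers: Iterable[str], k: int, source_id: str = "") -> "KmerSet":
        codes = [canonical_kmer_codes(s, k)[0] for s in kmers]
        arr = np.unique(np.asarray(codes, dtype=np.uint64)) if codes else np.empty(0, np.uint64)
        return cls(k=k, members=arr, source_id=source_id)


def canonical_kmers(sequence: str, k: int, source_id: str = "") -> KmerSet:
    """Canonical k-mer set of a sequence (non-ACGT windows skipped)."""
    return KmerSet.from_sequence(sequence, k, source_id)


def _check_comparable(ref_set: KmerSet, target_set: KmerSet) -> None:
    if ref_set.k != target_set.k:
        raise ValueError(f"k mismatch: {ref_set.k} vs {target_set.k}")


def containment(ref_set: KmerSet, target_set: KmerSet) -> float:
    """|ref ∩ target| / |ref| — fraction of the reference set present in the target.

    Raises ``ValueError`` on an empty reference set (callers record such cells
    as status "missing" rather than a score).
    """
    _check_comparable(ref_set, target_set)
    if len(ref_set) == 0:
        raise ValueError("containment undefined for an empty reference set")
    inter = np.intersect1d(ref_set.members, target_set.members, assume_unique=True)
    return inter.size / len(ref_set)


def jaccard(ref_set: KmerSet, target_set: KmerSet) -> float:
    """|ref ∩ target| / |ref ∪ target|."""
    _check_comparable(ref_set, target_set)
    union = np.union1d(ref_set.members, target_set.members)
    if union.size == 0:
        raise ValueError("jaccard undefined for two empty sets")
    inter = np.intersect1d(ref_set.members, target_set.members, assume_unique=True)
    return inter.size / union.size


def write_kmer_set(kmer_set: KmerSet, path: str | Path) -> None:
    """Serialize to a sorted plain-text file (one k-mer per line)."""
    with open(path, "w") as fh:
        fh.write(f"#k={kmer_set.k}\tsource={kmer_set.source_id}\tn={len(kmer_set)}\n")
        for kmer in kmer_set.kmers():
            fh.write(kmer + "\n")


def read_kmer_set(path: str | Path) -> KmerSet:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#k="):
            raise ValueError(f"{path}: not a k-mer set file")
        fields = dict(f.split("=", 1) for f in header[1:].rstrip("\n").split("\t"))
        k = int(fields["k"])
        kmers = [line.strip() for line in fh if line.strip()]
    return KmerSet.from_kmers(kmers, k, source_id=fields.get("source", ""))


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered {name: sequence} mapping."""
    from Bio import SeqIO

    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            warnings.warn(f"duplicate FASTA record id {rec.id!r}; keeping the first")
            continue
        records[rec.id] = str(rec.seq)
    return records


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
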