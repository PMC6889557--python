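import numpy as np
import pytest

BASES = "ACGT"


def random_dna(rng: np.random.Generator, length: int, alphabet: str = BASES) -> str:
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), size=length))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20231)


@pytest.fixture
def sam_header():
    import pysam

    return pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6"}, "SQ": [{"SN": "chrA", "LN": 100}, {"SN": "chrB", "LN": 60}]}
    )


def make_read(header, name, contig, start, seq, cigar=None, flag=0, mapq=60):
    """An in-memory aligned SAM record for alignment-projection tests."""
    import pysam

    rec = pysam.AlignedSegment(header)
    rec.query_name = name
    rec.query_sequence = seq
    rec.flag = flag
    rec.reference_id = header.references.index(contig) if contig is not None else -1
    rec.reference_start = start
    rec.mapping_quality = mapq
    rec.cigarstring = cigar or f"{len(seq)}M"
    return rec
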