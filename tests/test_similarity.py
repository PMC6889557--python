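"""Read-alignment k-mer set construction, matrix scoring and top calls."""

import math

import numpy as np
import pytest

from kmertrace.kmer import KmerSet, canonical_kmers
from kmertrace.partition import SubRegion, partition_reference
from kmertrace.similarity import (
    ASSIGNED,
    AMBIGUOUS,
    LOW_SIMILARITY,
    MISSING,
    SampleRegionSets,
    SimilarityMatrix,
    assign_top,
    read_matrix_tsv,
    read_region_sets,
    region_sets_from_alignments,
    region_sets_from_genome,
    reference_region_sets,
    score_matrix,
    write_matrix_tsv,
    write_region_sets,
)
from conftest import make_read, random_dna


REGIONS_A = [SubRegion("chrA", 0, 10), SubRegion("chrA", 10, 20)]


def test_projected_overlap_counts_kmers(sam_header):
    # perfect-match 10-base read at reference 4-13; region [0,10) overlaps
    # read bases 0-5 (6 bases) -> 6-3+1 = 4 three-mers
    read = make_read(sam_header, "r1", "chrA", 4, "AAACCCGGGG")
    sets = region_sets_from_alignments([read], REGIONS_A, k=3, sample_id="s")
    assert set(sets.sets["chrA:0-10"].kmers()) == set(canonical_kmers("AAACCC", 3).kmers())
    assert len(sets.sets["chrA:0-10"]) == 4
    assert sets.read_support["chrA:0-10"] == 6
    assert sets.read_support["chrA:10-20"] == 4


def test_read_spanning_boundary_feeds_both_regions(sam_header):
    read = make_read(sam_header, "r1", "chrA", 5, "ACGTACGTAC")  # spans 5..15
    sets = region_sets_from_alignments([read], REGIONS_A, k=3, sample_id="s")
    assert "chrA:0-10" in sets.sets and "chrA:10-20" in sets.sets
    # k-mers come from within-region substrings only
    assert set(sets.sets["chrA:0-10"].kmers()) == set(canonical_kmers("ACGTA", 3).kmers())
    assert set(sets.sets["chrA:10-20"].kmers()) == set(canonical_kmers("CGTAC", 3).kmers())


def test_unmapped_secondary_supplementary_ignored(sam_header):
    reads = [
        make_read(sam_header, "u", None, -1, "ACGTACGTAC", flag=4, cigar="*"),
        make_read(sam_header, "sec", "chrA", 0, "ACGTACGTAC", flag=256),
        make_read(sam_header, "sup", "chrA", 0, "ACGTACGTAC", flag=2048),
    ]
    sets = region_sets_from_alignments(reads, REGIONS_A, k=3, sample_id="s")
    assert sets.sets == {}


def test_insertion_and_softclip_respected(sam_header):
    # 4M2I4M: read bases 4..5 are an insertion, absent from the reference
    read = make_read(sam_header, "r1", "chrA", 0, "AAAACCGGGG", cigar="4M2I4M")
    sets = region_sets_from_alignments([read], REGIONS_A, k=4, sample_id="s")
    expected = set(canonical_kmers("AAAA", 4).kmers()) | set(canonical_kmers("GGGG", 4).kmers())
    assert set(sets.sets["chrA:0-10"].kmers()) == expected


def test_contig_absent_from_partition_warns_and_skips(sam_header):
    read = make_read(sam_header, "r1", "chrB", 0, "ACGTACGTAC")
    with pytest.warns(UserWarning, match="absent"):
        sets = region_sets_from_alignments([read], REGIONS_A, k=3, sample_id="s")
    assert sets.skipped_records == 1 and sets.sets == {}


def test_region_sets_from_genome_identity(rng):
    genome = {"chrA": random_dna(rng, 5000)}
    regions = partition_reference({"chrA": 5000}, region_size=1000)
    ref = reference_region_sets(genome, regions, k=21)
    panel = [region_sets_from_genome(genome, regions, 21, sample_id="self")]
    matrix = score_matrix(ref, panel)
    assert np.allclose(matrix.scores, 1.0)


def test_region_sets_from_genome_divergence_lowers_containment(rng):
    genome = {"chrA": random_dna(rng, 5000)}
    mutated = list(genome["chrA"])
    for pos in rng.choice(5000, size=50, replace=False):  # 1% divergence
        mutated[pos] = "ACGT"[("ACGT".index(mutated[pos]) + 1) % 4]
    regions = partition_reference({"chrA": 5000}, region_size=1000)
    ref = reference_region_sets(genome, regions, k=21)
    panel = [region_sets_from_genome({"chrA": "".join(mutated)}, regions, 21, sample_id="mut")]
    matrix = score_matrix(ref, panel)
    # every 1000-bp window carries ~10 substitutions; each kills up to 21 ref k-mers
    assert np.all(matrix.scores < 1.0)
    assert np.all(matrix.scores > 0.5)


def test_region_sets_from_genome_missing_contig_errors():
    with pytest.raises(KeyError):
        region_sets_from_genome({"other": "ACGT" * 100}, REGIONS_A, 3)


def test_score_matrix_matches_brute_force_sets():
    ref = {
        "r1": KmerSet.from_kmers(["AAAA", "AACA", "AACC", "AACG"], 4),
        "r2": KmerSet.from_kmers(["GGGG", "GGGC"], 4),
    }
    s1 = SampleRegionSets("s1", 4, sets={"r1": KmerSet.from_kmers(["AAAA", "AACA", "TTTT"], 4)})
    s2 = SampleRegionSets("s2", 4, sets={"r1": KmerSet.from_kmers(["AAAA"], 4), "r2": KmerSet.from_kmers(["GGGG", "GGGC"], 4)})
    matrix = score_matrix(ref, [s1, s2])
    assert matrix.scores[0, 0] == pytest.approx(2 / 4)
    assert matrix.scores[0, 1] == pytest.approx(1 / 4)
    assert math.isnan(matrix.scores[1, 0])  # s1 has no set for r2 -> missing
    assert matrix.status(1, 0) == MISSING
    assert matrix.scores[1, 1] == pytest.approx(1.0)


def test_score_matrix_empty_panel_errors():
    with pytest.raises(ValueError):
        score_matrix({"r1": KmerSet.from_kmers(["AAAA"], 4)}, [])


def test_adding_reads_never_decreases_containment(sam_header, rng):
    genome = random_dna(rng, 100)
    regions = [SubRegion("chrA", 0, 100)]
    ref = reference_region_sets({"chrA": genome}, regions, k=5)
    reads = [
        make_read(sam_header, f"r{i}", "chrA", int(start), genome[start : start + 20])
        for i, start in enumerate(rng.integers(0, 80, size=12))
    ]
    prev = 0.0
    for n in range(1, len(reads) + 1):
        sets = region_sets_from_alignments(reads[:n], regions, 5, sample_id="s")
        score = score_matrix(ref, [sets]).scores[0, 0]
        assert score >= prev - 1e-12
        prev = score


def test_assign_top_tie_low_similarity_and_ambiguity():
    matrix = SimilarityMatrix(
        region_ids=["r1", "r2", "r3", "r4"],
        sample_ids=["s1", "s2", "s3"],
        scores=np.array(
            [
                [0.9, 0.9, 0.5],  # exact tie within one lineage set
                [0.4, 0.2, 0.1],  # below the similarity floor
                [0.95, 0.95, 0.5],  # tie across lineages
                [np.nan, np.nan, np.nan],  # nothing scored
            ]
        ),
    )
    lineages = {"s1": "L1", "s2": "L1", "s3": "L2"}
    calls = assign_top(matrix, lineages, min_similarity=0.75)
    assert calls[0].status == ASSIGNED and calls[0].top_samples == {"s1", "s2"}
    assert calls[1].status == LOW_SIMILARITY and calls[1].top_samples == frozenset()
    assert calls[1].max_score == pytest.approx(0.4)
    lineages_cross = {"s1": "L1", "s2": "L2", "s3": "L3"}
    calls_cross = assign_top(matrix, lineages_cross, min_similarity=0.75)
    assert calls_cross[2].status == AMBIGUOUS and calls_cross[2].lineages == {"L1", "L2"}
    assert calls[3].status == MISSING and math.isnan(calls[3].max_score)


def test_assign_top_tie_delta_widens_winners():
    matrix = SimilarityMatrix(["r1"], ["s1", "s2"], np.array([[0.90, 0.88]]))
    lineages = {"s1": "L1", "s2": "L1"}
    assert assign_top(matrix, lineages)[0].top_samples == {"s1"}
    assert assign_top(matrix, lineages, tie_delta=0.05)[0].top_samples == {"s1", "s2"}


def test_assign_top_requires_lineages():
    matrix = SimilarityMatrix(["r1"], ["s1"], np.array([[0.9]]))
    with pytest.raises(KeyError):
        assign_top(matrix, {})


def test_matrix_tsv_roundtrip(tmp_path):
    matrix = SimilarityMatrix(["r1", "r2"], ["s1", "s2"], np.array([[1.0, 0.5], [np.nan, 0.25]]))
    path = tmp_path / "matrix.tsv"
    write_matrix_tsv(matrix, path, header="params here")
    back = read_matrix_tsv(path)
    assert back.region_ids == matrix.region_ids and back.sample_ids == matrix.sample_ids
    assert np.allclose(back.scores, matrix.scores, equal_nan=True)


def test_region_sets_file_roundtrip(tmp_path, rng):
    genome = {"chrA": random_dna(rng, 3000)}
    regions = partition_reference({"chrA": 3000}, region_size=1000)
    sample = region_sets_from_genome(genome, regions, 21, sample_id="sX")
    path = tmp_path / "sets.txt"
    write_region_sets(sample, path)
    back = read_region_sets(path)
    assert back.sample_id == "sX" and back.k == 21
    assert back.sets.keys() == sample.sets.keys()
    for rid in sample.sets:
        assert np.array_equal(back.sets[rid].members, sample.sets[rid].members)
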