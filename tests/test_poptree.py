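"""MinHash sketching, Mash distances, UPGMA trees and winner tracing."""

import numpy as np
import pytest

from kmertrace.kmer import canonical_kmers, jaccard
from kmertrace.poptree import (
    PopulationTree,
    annotated_newick,
    count_kmers,
    mash_distance,
    mash_distance_matrix,
    minhash_sketch,
    neighbor_joining,
    read_lineage_map,
    read_sketch,
    sketch_from_sequences,
    sketch_jaccard,
    trace,
    unrecovered_clades,
    upgma,
    write_sketch,
)
from kmertrace.similarity import Assignment, ASSIGNED, AMBIGUOUS, LOW_SIMILARITY
from kmertrace.synthetic import simulate_panel
from conftest import random_dna


def test_count_kmers_multiplicities():
    codes, counts = count_kmers(["AAAA", "AAA"], 3)  # AAA occurs 2+1 times
    assert codes.size == 1 and counts[0] == 3


def test_minhash_small_input_keeps_all_hashes(rng):
    seq = random_dna(rng, 500)
    sketch = sketch_from_sequences([seq, seq], k=21, sketch_size=10_000, min_freq=2, sample_id="s")
    n_distinct = canonical_kmers(seq, 21).members.size
    assert sketch.hashes.size == n_distinct  # all below sketch_size retained
    assert np.all(np.diff(sketch.hashes.astype(np.int64)) > 0)  # sorted, distinct


def test_minhash_min_freq_drops_singletons(rng):
    a, b = random_dna(rng, 300), random_dna(rng, 300)
    sketch = sketch_from_sequences([a, a, b], k=21, min_freq=2, sample_id="s")
    only_a = sketch_from_sequences([a], k=21, min_freq=1, sample_id="a")
    assert np.array_equal(sketch.hashes, only_a.hashes)  # b's singletons dropped


def test_minhash_determinism_and_sketch_size_cap(rng):
    seq = random_dna(rng, 2000)
    s1 = sketch_from_sequences([seq], k=21, sketch_size=100, min_freq=1, sample_id="s")
    s2 = sketch_from_sequences([seq], k=21, sketch_size=100, min_freq=1, sample_id="s")
    assert np.array_equal(s1.hashes, s2.hashes) and s1.hashes.size == 100


def test_minhash_empty_after_filter_warns():
    with pytest.warns(UserWarning, match="empty sketch"):
        sketch = minhash_sketch(count_kmers(["AAACCCTTT"], 5), min_freq=2, k=5, sample_id="s")
    assert sketch.hashes.size == 0


def test_sketch_jaccard_exact_on_unsketched_sets(rng):
    a, b = random_dna(rng, 800), random_dna(rng, 800)
    mixed = a[:400] + b[400:]
    sk_a = sketch_from_sequences([a], k=11, min_freq=1, sample_id="a")
    sk_m = sketch_from_sequences([mixed], k=11, min_freq=1, sample_id="m")
    exact = jaccard(canonical_kmers(a, 11), canonical_kmers(mixed, 11))
    assert sketch_jaccard(sk_a, sk_m) == pytest.approx(exact)
    assert sketch_jaccard(sk_a, sk_a) == 1.0


def test_sketch_jaccard_estimate_close_on_100kb_genomes():
    rng = np.random.default_rng(7)
    a = random_dna(rng, 100_000)
    b = a[:60_000] + random_dna(rng, 40_000)
    sk_a = sketch_from_sequences([a], k=21, sketch_size=1000, min_freq=1, sample_id="a")
    sk_b = sketch_from_sequences([b], k=21, sketch_size=1000, min_freq=1, sample_id="b")
    exact = jaccard(canonical_kmers(a, 21), canonical_kmers(b, 21))
    assert sketch_jaccard(sk_a, sk_b) == pytest.approx(exact, abs=0.05)


def test_sketch_jaccard_disjoint_is_zero(rng):
    sk_a = sketch_from_sequences(["A" * 50], k=21, min_freq=1, sample_id="a")
    sk_b = sketch_from_sequences(["C" * 50], k=21, min_freq=1, sample_id="b")
    assert sketch_jaccard(sk_a, sk_b) == 0.0


@pytest.mark.parametrize(
    "j, k, expected",
    [
        (1.0, 21, 0.0),
        (0.0, 21, 1.0),  # cap convention
        (0.9, 21, 0.0025746),
    ],
)
def test_mash_distance_closed_form(j, k, expected):
    assert mash_distance(j, k) == pytest.approx(expected, abs=1e-6)


def test_mash_distance_rejects_out_of_range():
    with pytest.raises(ValueError):
        mash_distance(1.5, 21)


def test_upgma_three_taxon_worked_example():
    dist = np.array([[0.0, 0.2, 0.6], [0.2, 0.0, 0.6], [0.6, 0.6, 0.0]])
    tree = upgma(dist, ["A", "B", "C"])
    assert tree.to_newick() == "((A:0.1,B:0.1):0.2,C:0.3);"


def test_upgma_two_taxa():
    tree = upgma(np.array([[0.0, 0.4], [0.4, 0.0]]), ["B", "A"])
    assert tree.to_newick() == "(A:0.2,B:0.2);"


def test_upgma_reproduces_ultrametric_input():
    # distances generated by an ultrametric tree are a UPGMA fixed point
    dist = np.array(
        [
            [0.0, 0.2, 0.8, 0.8],
            [0.2, 0.0, 0.8, 0.8],
            [0.8, 0.8, 0.0, 0.4],
            [0.8, 0.8, 0.4, 0.0],
        ]
    )
    tree = upgma(dist, ["A", "B", "C", "D"])
    assert tree.to_newick() == "((A:0.1,B:0.1):0.3,(C:0.2,D:0.2):0.2);"


def test_upgma_rejects_non_symmetric():
    with pytest.raises(ValueError):
        upgma(np.array([[0.0, 0.1], [0.2, 0.0]]), ["A", "B"])


def test_neighbor_joining_recovers_split():
    dist = np.array([[0.0, 0.2, 0.6], [0.2, 0.0, 0.6], [0.6, 0.6, 0.0]])
    tree = neighbor_joining(dist, ["A", "B", "C"])
    assert set(tree.leaf_labels) == {"A", "B", "C"}


def test_upgma_on_mash_recovers_lineages():
    _, genomes, truth = simulate_panel(3, 2, [60_000], within_div=0.003, between_div=0.02, seed=3)
    sketches = [
        sketch_from_sequences(genomes[s].values(), k=21, min_freq=1, sample_id=s) for s in sorted(genomes)
    ]
    labels, dist = mash_distance_matrix(sketches)
    tree = upgma(dist, labels)
    truth_tree = PopulationTree.from_newick(truth.tree_newick)
    assert unrecovered_clades(truth_tree, tree) == 0


def test_unrecovered_clades_zero_for_identical_trees():
    t = PopulationTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
    assert unrecovered_clades(t, t) == 0
    other = PopulationTree.from_newick("((A:1,C:1):1,(B:1,D:1):1);")
    assert unrecovered_clades(t, other) > 0


def _toy_tree():
    tree = PopulationTree.from_newick("((s1:1,s2:1):1,s3:2);")
    tree.lineage_map = {"s1": "L1", "s2": "L1", "s3": "L2"}
    return tree


def test_trace_counts_and_total():
    calls = [
        Assignment("r1", ASSIGNED, 0.9, frozenset({"s1"}), frozenset({"L1"})),
        Assignment("r2", ASSIGNED, 0.8, frozenset({"s1"}), frozenset({"L1"})),
        Assignment("r3", ASSIGNED, 0.9, frozenset({"s2"}), frozenset({"L1"})),
        Assignment("r4", AMBIGUOUS, 0.9, frozenset({"s2", "s3"}), frozenset({"L1", "L2"})),
        Assignment("r5", LOW_SIMILARITY, 0.3),
    ]
    result = trace(calls, _toy_tree())
    assert result.leaf_counts == {"s1": 2, "s2": 2, "s3": 1}
    assert result.N == 5 == sum(len(c.top_samples) for c in calls)  # ties count once each
    assert result.lineage_counts == {"L1": 4, "L2": 1}
    assert result.unassigned == {"low_similarity": 1}
    # internal node counts are descendant sums: root=5, (s1,s2)=4
    assert sorted(result.node_counts.values(), reverse=True) == [5, 4]


def test_trace_all_low_similarity_gives_empty_total():
    calls = [Assignment(f"r{i}", LOW_SIMILARITY, 0.1) for i in range(4)]
    result = trace(calls, _toy_tree())
    assert result.N == 0 and result.unassigned == {"low_similarity": 4}
    assert all(c == 0 for c in result.leaf_counts.values())


def test_trace_unknown_winner_errors():
    calls = [Assignment("r1", ASSIGNED, 0.9, frozenset({"sX"}), frozenset({"L1"}))]
    with pytest.raises(ValueError, match="sX"):
        trace(calls, _toy_tree())


def test_annotated_newick_mentions_counts():
    calls = [Assignment("r1", ASSIGNED, 0.9, frozenset({"s1"}), frozenset({"L1"}))]
    tree = _toy_tree()
    text = annotated_newick(tree, trace(calls, tree))
    assert "count" in text and "s1" in text


def test_sketch_file_roundtrip(tmp_path, rng):
    sketch = sketch_from_sequences([random_dna(rng, 400)], k=21, sketch_size=64, min_freq=1, sample_id="sZ")
    path = tmp_path / "sketch.txt"
    write_sketch(sketch, path)
    back = read_sketch(path)
    assert back.sample_id == "sZ" and back.k == 21 and back.sketch_size == 64
    assert back.min_freq == 1 and back.hash_seed == sketch.hash_seed
    assert np.array_equal(back.hashes, sketch.hashes)


def test_read_lineage_map(tmp_path):
    path = tmp_path / "lineages.tsv"
    path.write_text("#header\ns1\tBeer1\ns2\tWine\n")
    assert read_lineage_map(path) == {"s1": "Beer1", "s2": "Wine"}
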