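"""End-to-end admixture benchmark: simulate, score, assign, trace, evaluate.

This drives the whole toolkit over one synthetic experiment that mirrors the
intended use: a panel of strains with lineage structure, an admixed query
copied from two donors in different lineages, sequencing reads for every
panel strain aligned back to the query reference, per-sub-region containment
scoring, and tracing of the winners onto the UPGMA/Mash population tree.
Because the simulation records ground truth, the run reports how well each
stage recovered it — the per-donor assignment accuracy, the donor genome
fractions, and whether every true lineage clade appears in the inferred tree.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass, field
from pathlib import Path

from . import partition as _partition
from . import poptree as _poptree
from . import similarity as _similarity
from . import synthetic as _synthetic

__all__ = ["AdmixtureBenchmark", "run_admixture_benchmark"]


@dataclass
class AdmixtureBenchmark:
    """Outcome of one simulated admixture-recovery experiment."""

    seed: int
    n_regions: int
    n_informative: int  # non-breakpoint regions (single true donor)
    n_correct: int  # informative regions assigned exactly {true donor}
    donor_accuracy: float
    true_donor_fractions: dict[str, float]  # over informative regions
    traced_lineage_fractions: dict[str, float]
    donor_fraction_error: float  # max abs deviation, traced vs truth, in fraction
    unrecovered_clades: int  # 0 <=> every true lineage monophyletic in the tree
    N: int  # total winner count over all traced regions
    unassigned: dict[str, int] = field(default_factory=dict)
    tree_newick: str = ""


def run_admixture_benchmark(
    seed: int = 0,
    n_lineages: int = 5,
    strains_per_lineage: int = 3,
    genome_length: int = 200_000,
    within_div: float = 0.003,
    between_div: float = 0.02,
    donor1: str = "L1S1",
    donor2: str = "L3S2",
    breakpoint: int = 121_000,
    coverage: float = 30.0,
    read_len: int = 150,
    err: float = 0.002,
    region_size: int = 2000,
    k: int = 21,
    min_similarity: float = 0.75,
    workdir: str | Path | None = None,
) -> AdmixtureBenchmark:
    """Run the full simulate -> score -> assign -> trace pipeline and grade it.

    The query genome is a two-donor mosaic (``donor1`` up to ``breakpoint``,
    ``donor2`` after) and serves as the reference; panel k-mer sets are built
    from simulated reads aligned to it. All randomness derives from ``seed``.
    Intermediate SAM files go to ``workdir`` (a temporary directory by
    default).
    """
    contig = "chr01"
    ancestor, genomes, truth = _synthetic.simulate_panel(
        n_lineages, strains_per_lineage, {contig: genome_length}, within_div, between_div, seed=seed
    )
    if truth.lineage_map[donor1] == truth.lineage_map[donor2]:
        raise ValueError("donors must come from different lineages")
    segments = [(contig, 0, breakpoint, donor1), (contig, breakpoint, genome_length, donor2)]
    query, qtruth = _synthetic.simulate_admixed_query(genomes, segments, seed=seed + 1)

    regions = _partition.partition_reference({contig: genome_length}, region_size=region_size, k=k)
    ref_sets = _similarity.reference_region_sets(query, regions, k)

    own_dir = workdir is None
    tmp = Path(tempfile.mkdtemp(prefix="kmertrace-bench-")) if own_dir else Path(workdir)
    tmp.mkdir(parents=True, exist_ok=True)
    panel = []
    for i, sample in enumerate(sorted(genomes)):
        sam = tmp / f"reads_{sample}.sam"
        _synthetic.simulate_reads(
            genomes[sample], coverage=coverage, read_len=read_len, err=err,
            seed=seed + 100 + i, out_sam=sam, sample_name=sample,
        )
        panel.append(_similarity.region_sets_from_alignments(sam, regions, k, sample_id=sample))
        if own_dir:
            sam.unlink()

    matrix = _similarity.score_matrix(ref_sets, panel)
    calls = _similarity.assign_top(matrix, truth.lineage_map, min_similarity=min_similarity)

    by_id = {r.id: r for r in regions}
    n_informative = n_correct = 0
    donor_regions = {donor1: 0, donor2: 0}
    for call in calls:
        r = by_id[call.region_id]
        donor = qtruth.donor_of(r.contig, r.start, r.end)
        if donor is None:  # breakpoint region
            continue
        n_informative += 1
        donor_regions[donor] += 1
        if call.status == _similarity.ASSIGNED and call.top_samples == frozenset({donor}):
            n_correct += 1
    true_fracs = {d: n / n_informative for d, n in donor_regions.items()}

    sketches = [
        _poptree.sketch_from_sequences(genomes[s].values(), k=k, min_freq=1, sample_id=s)
        for s in sorted(genomes)
    ]
    labels, dist = _poptree.mash_distance_matrix(sketches)
    tree = _poptree.upgma(dist, labels)
    tree.lineage_map = dict(truth.lineage_map)
    truth_tree = _poptree.PopulationTree.from_newick(truth.tree_newick, truth.lineage_map)
    fn = _poptree.unrecovered_clades(truth_tree, tree)

    result = _poptree.trace(calls, tree)
    traced_fracs = result.lineage_fractions()
    err_frac = max(
        abs(traced_fracs.get(truth.lineage_map[d], 0.0) - true_fracs[d]) for d in (donor1, donor2)
    )
    return AdmixtureBenchmark(
        seed=seed,
        n_regions=len(regions),
        n_informative=n_informative,
        n_correct=n_correct,
        donor_accuracy=n_correct / n_informative if n_informative else 0.0,
        true_donor_fractions=true_fracs,
        traced_lineage_fractions=traced_fracs,
        donor_fraction_error=err_frac,
        unrecovered_clades=fn,
        N=result.N,
        unassigned=result.unassigned,
        tree_newick=tree.to_newick(),
    )
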