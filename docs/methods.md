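# Methods

## Model and rationale

A single phylogeny cannot describe a genome whose chromosomal segments have
different population origins (interspecies hybrids, admixed strains,
horizontally transferred regions). `kmertrace` therefore scores similarity
*locally*: the reference genome is tiled into fixed-size sub-regions, each
reduced to a canonical k-mer set, and each sub-region is compared
independently against every strain of a reference panel. The population
origin of each sub-region is then read off a population tree as the
lineage of the top-scoring strain(s). The per-sub-region decision is
deliberately model-free — no recombination map, no HMM smoothing — which
keeps it cheap and assumption-light; the cost is that each 2-kb window is
decided in isolation (see Limitations).

### Similarity statistic

For reference sub-region set *R* and sample set *S* (same k), similarity is
the containment `|R ∩ S| / |R|`. Containment rather than Jaccard is the
default because panel sets are built from reads: at higher depth a sample
accumulates extra (e.g. error) k-mers that would dilute a Jaccard score but
leave containment untouched, whereas missing coverage lowers both. Jaccard
is available via `score_matrix(..., metric="jaccard")`. Cells where either
set is empty carry status `missing`, never a numeric score.

With substitution divergence *d* per site, a random 21-mer survives
untouched with probability ≈ (1 − d)^21, so containment against a strain at
0.6% divergence is ≈ 0.88 while the true donor (identical sequence, 30×
reads at 0.2% error) scores ≈ 1.0 — a wide margin that makes the per-region
argmax reliable at the study's divergence scales.

### Panel sets from alignments

Panel k-mer sets are derived from read alignments only, projected onto the
reference partition, so every genome is compared over exactly the same
intervals regardless of its own assembly structure. Only primary mapped
records contribute; match/mismatch CIGAR blocks are projected onto reference
coordinates and the read substring falling inside a sub-region yields its
canonical k-mers. K-mers spanning an indel or a region boundary are not
generated (each would belong to no single region); with 2-kb regions and
21-mers this loses ≤ 1% of positions per boundary. Duplicates are not
detected and base qualities are not consulted — trimming/deduplication is
upstream of this tool.

### Assignment

Per sub-region, all samples scoring within `tie_delta` (default 0 — exact
ties) of the maximum win. If the maximum is below `min_similarity`
(default 0.75) the region is `low_similarity` and carries no winners; if
the winners span more than one lineage the region is `ambiguous_lineage`.
Both thresholds are configurable and recorded in output headers; 0.75 sits
between the ≈ 0.88 same-lineage and ≈ 1.0 true-donor containments above, so
it only suppresses regions with no close relative in the panel. Tied winners
each count once in the trace total N.

### Population tree

Panel genomes are summarised by bottom-k MinHash sketches: canonical k-mers
with multiplicity below `min_freq` are discarded (default 2 — with read
input this removes most error k-mers; for assemblies use 1), the rest are
hashed with a fixed-seed splitmix64 finalizer (seed recorded in sketch
files), and the `sketch_size` (default 1,000,000) smallest distinct hashes
are kept. The merged bottom-sketch estimator gives the Jaccard index, exact
whenever the genomes have fewer distinct k-mers than the sketch size;
Mash distance `d = −(1/k)·ln(2j/(1+j))` (capped at 1 as j → 0) converts it
to an approximate per-base mutation rate. Trees are built by UPGMA
(average linkage; merge at distance *d* places the node at height *d*/2;
equal-distance merges broken by the lexicographically smallest pair of
cluster representatives, children ordered by smallest leaf label — output
is fully deterministic). UPGMA is the default because its ultrametric
output matches a population-tree display; neighbor joining is provided as
an alternative, and externally supplied newick trees (published lineage
trees) bypass clustering entirely.

### Tracing

Winners are aggregated over all sub-regions: each leaf's count is the number
of regions it (co-)won, internal nodes carry descendant sums, lineages sum
their member leaves, and N is the grand total (Σ over regions of the number
of winners). Low-similarity and missing regions are tallied separately, not
in N.

## Companion analyses

**Chromosome copy number.** Per-base depth → median per non-overlapping
100-bp window (even-count medians average the two middle values; trailing
partial windows included) → per-chromosome median of window medians →
copy number = round(baseline_ploidy × median / smallest positive chromosome
median). Rounding is conventional (half away from zero). Fixed-copy
sub-regions for the gene-level test can be supplied by the user or derived
by segmenting the per-window copy-number track at integer-level changes.

**Gene-level deviation.** z = (gene mean − region mean) / region sd, with a
two-sided normal tail p-value, uncorrected; genes are flagged at p < 0.05.
Two-sided because both gains and losses are of interest; a zero-sd region
makes the gene untestable rather than infinitely significant.

**Heterozygous-SNP filter.** A call survives iff its 1-based position lies
in `(end_excl, L − end_excl]` (default 10 kb), minor-allele frequency
≥ 0.15 and depth ≥ 3. Thresholds phrased as "below X" are strict
exclusions, so boundary values (MAF exactly 0.15, depth exactly 3) are kept.

**Tandem repeats.** Repeat units are aligned locally against each gene on
both strands with an internal aligner (match +1, mismatch −1, gap −2),
enumerating multiple copies by iteratively recording and masking the best
hit. A hit is kept at identity ≥ 0.7 (no identity threshold is canonical
for this analysis; 0.7 tolerates the divergence seen between repeat copies
while rejecting random matches) and the search stops below a score floor of
max(10, unit length / 4), which terminates the scan and suppresses the short
spurious local alignments expected between unrelated sequences. Hits with
unit coverage < 0.5 are discarded; survivors are chained while consecutive
gaps are ≤ 3 × unit length (a strictly larger gap starts a new cluster);
copies = cluster span / unit length, reported to one decimal — fractional
values are genuine, reflecting partial copies at array edges. When several
clusters exist the table reports the largest; all are available
programmatically.

## Synthetic data: what it emulates and what it does not

`simulate_panel` draws a uniform-random ancestor, lineage founders at
`between_div` (default 0.02) substitutions/site from the ancestor and
strains at `within_div` (default 0.003) from their founders — divergences
chosen to bracket the within/between-population distances typical of
domesticated yeast panels while keeping a 3× separation so lineages are
cleanly resolvable. Queries are segment-wise copies of donor strains
(`simulate_admixed_query`), optionally with private substitutions. Reads
(default 30×, 150 bp, 0.2% substitution error) are emitted as SAM records
at their true positions — alignment is by construction, not inference.
Depth tracks are Poisson per base; repeat genes are exact unit
concatenations with random spacers.

The mutation model is substitution-only: every genome stays colinear with
the ancestor, so ground truth projects exactly onto reference coordinates
and panel sets can also be built directly from genome sequence in tests.
Real data differ in ways the simulation does not capture: indels and
structural variation, alignment/mapping error, GC- and repeat-driven
coverage bias, quality-dependent error profiles, and contamination. Passing
tests therefore demonstrate the correctness of the computations and the
recoverability of planted signal under idealised conditions — not
performance on real libraries, where alignment quality dominates.

The generating tree is a star of lineage clades, each a star of strains
(founders and strains drawn i.i.d.), so within-lineage topology is
deliberately unresolved. Tree recovery is accordingly measured as the
number of generating clades missing from the UPGMA tree (the
false-negative half of the Robinson–Foulds symmetric difference): 0 means
every lineage is recovered monophyletic, while the extra resolution any
binary tree adds inside a lineage is not penalised. For two fully resolved
trees the measure reduces to the usual RF test of identity.

## Benchmark problem sizes

The end-to-end benchmark (`kmertrace.pipeline.run_admixture_benchmark`, also
driven by `scripts/acceptance.py` and the test suite) uses a 200-kb
single-contig genome, 5 lineages × 3 strains, a two-donor 60/40 mosaic with
the breakpoint at 121 kb (deliberately not a multiple of the 2-kb region
size, so exactly one region straddles it and 99 informative regions remain),
30× reads per panel strain and sketch parameters k = 21 / min_freq 1 (panel
assemblies). These sizes exercise every stage at realistic per-window k-mer
densities while completing in minutes on one CPU; accuracy is insensitive to
genome length beyond a few hundred windows because each sub-region is an
independent trial.

## Numerical and degenerate-input choices

- K-mers are 2-bit packed into uint64 (k ≤ 31); extraction is vectorised
  and windows containing non-ACGT symbols are skipped rather than recoded.
- `k > len(sequence)` yields an empty set, not an error; an empty *reference*
  set in a comparison is an error at the function level and a `missing`
  cell at the matrix level.
- Trailing partition windows shorter than k are dropped (they cannot hold a
  single k-mer); trailing windows ≥ k are kept so subtelomeric sequence is
  not lost. Tiling is otherwise exact and gap-free.
- Mash distance at j = 0 is capped at 1; UPGMA rejects asymmetric matrices.
- All simulation randomness flows through one `numpy` Generator per
  operation, seeded explicitly; seeds are recorded in truth objects and
  reruns are byte-identical.

## Known limitations

- Sub-regions are assigned independently; no spatial smoothing across
  windows, so isolated misassignments are not corrected by context.
- Read-alignment k-mer extraction skips k-mers spanning indels and region
  boundaries; for very small regions (≈ k) this loss becomes material.
- `region_sets_from_genome` on a non-reference genome assumes colinearity
  and is intended for the synthetic, substitution-only setting; real panel
  genomes should be introduced via read alignments.
- The repeat aligner is exact but O(gene × unit) per iteration with one
  iteration per copy; it is meant for gene-scale inputs (kb), not
  chromosome scans.
- MinHash sketching of read sets filters singleton k-mers, which at very low
  coverage (< ~5×) also removes genuine k-mers and inflates distances.
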