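# Methods

## The model

combipool implements a two-stage pooled sequencing design for
reconstructing many bacterial genomes from few libraries, plus the
downstream use of the reconstructed catalog for metagenomic profiling.

**Pool design.** Strains are partitioned into assembly pools under a
genus-disjointness constraint (mixing near-identical genomes degrades
co-assembly). Placement is a largest-genus-first greedy that always
takes the currently least-loaded pools, which keeps pool sizes within
±1 whenever the constraint allows. Combinatorial signatures are chosen
from the `2^P − 1` nonzero binary patterns over the `P` combinatorial
pools: patterns are enumerated in Gray-code order, shuffled with the
seed, then stably sorted by distance of their popcount from `P/2` and
taken first-k. This guarantees uniqueness without rejection sampling
and prefers balanced patterns, which spread DNA mass evenly over pools.
Uniqueness is enforced per assembly pool, not globally, because each
assembly pool's coverage matrix is deconvolved independently.

**Coverage matrix.** Depth is expressed as mean fold coverage (mapped
bases / contig length), which is robust to read-length differences
between sequencing platforms. Contigs shorter than 100 bp are
discarded. An optional per-pool normalization divides each pool's
column by that pool's total mapped bases and rescales by the mean pool
total. This removes per-pool *yield* differences, but the pool total
also scales with pool *membership* (how much genomic mass was pooled),
so on small or strongly unbalanced designs — including the synthetic
pools generated here, which have equal yield by construction —
normalization distorts the correlation against the binary signature
and should be off. The library function defaults to normalization on
(real pools have uneven yield); the synthetic workflows and the
pipeline examples set `normalize_depths` explicitly.

**Deconvolution.** Each contig's coverage vector is correlated
(Pearson) against every candidate strain's binary signature. The
contig goes to the argmax strain iff `max r ≥ r_min` (default 0.95)
and the maximum is unique; ties within `1e−12` are unassigned (a
contig equally correlated with two signatures is unidentifiable), and
constant coverage vectors — whose correlation is undefined — are
unassigned rather than an error, since real pools produce such rows.
Correlation is computed against the binary signature directly, not a
depth-weighted one. Pearson's affine invariance makes assignments
invariant under positive rescaling of a coverage row.

**Draft quality.** Six HMP submission criteria (contig N90 ≥ 500 bp,
≥ 90% of the 99 bacterial essential genes, ≥ 90% of assembly bases at
more than 5-fold coverage — read strictly, depth > 5 —, contig N50 ≥
5 kb, scaffold N50 ≥ 20 kb, mean contig ≥ 5 kb) plus two chimera
tests. The tetranucleotide test computes, per contig, the 256-long
4-mer frequency vector (overlapping windows, counted on the given
strand without reverse-complement collapsing — strand is fixed by the
assembly; windows containing non-ACGT characters are dropped; the
denominator is the sequence length) and flags the draft when the mean
pairwise Spearman ρ falls below 0.6. Only contigs ≥ 1 kb enter this
test: shorter contigs give noisy rank correlations. The marker test
counts the 40 universally single-copy phylogenetic protein families
found ≥ 2 times (hits below 50% identity or 50% coverage are ignored)
and calls the draft chimeric at ≥ 3 duplicated markers. Tiers:
`excluded` (< 1 Mb cumulative contigs or either chimera test fails),
`standard` (chimera clean, essential set incomplete), `near_complete`
(chimera + essential pass, some contiguity criterion fails),
`high_quality` (everything passes). Two "absence of evidence" cases
count as a pass with a warning rather than a failure: a draft with
fewer than two eligible contigs has no tetranucleotide evidence, and a
draft without per-base depths has no coverage-fraction evidence.
Essential-gene pass means fraction ≥ 0.90 of the 99-gene catalog,
i.e. at least 90 genes. Cluster purity is length-weighted: the
dominant genus is the one with maximal mapped length; unassigned
contigs count toward it (they carry no evidence of mis-assignment),
while contigs mapped to another genus measure potential
mis-assignment. Clusters under 500 kb are skipped as too fragmented to
judge.

**Profiling.** Reads with mean base quality strictly below 20 are
discarded. Informative features are CDS minus mobile elements
(case-insensitive substring match on transposase / integrase / phage /
prophage / plasmid; "IS" only as a standalone token so words like
"histidine" don't match); intergenic, tRNA and rRNA features are
masked. Unannotated genomes are cut into 1000-base fragments, keeping
the final partial fragment (dropping it would bias small replicons).
Coordinates are 0-based half-open throughout; breadth, depth and
perfect-match metrics are computed over the union of informative
feature intervals, with each read covering `[position, position +
read_length)` (default 50 nt, typical short single-end reads — the
read table may carry the true aligned length). Candidate genomes need
≥ 20% of features covered; survivors need ≥ 700 reads and ≥ 20% CDS
breadth. Presence: with `avg` = reads per CDS, present iff `avg ≥ 10`
and breadth > 80%, or `2 ≤ avg < 10` and breadth > 70% — "between 2
and 10" is read as the half-open interval so the branches partition
cleanly at 10 (configurable). Species deduplication keeps the
reference with the highest CDS breadth, ties broken by lexicographic
genome id for determinism. Relative abundance divides a genome's reads
by the total good-quality reads; multi-mapping reads are counted as
the mapper reported them, once per genome before deduplication.

## The synthetic-data generator

The generator emulates: compositionally distinct genomes (each strain
gets its own order-3 Markov transition table, Dirichlet-sampled, or a
GC-bias i.i.d. model — this separability is exactly what the
tetranucleotide chimera test relies on), assembly fragmentation
(jittered tiling that conserves the genome and respects the 100 bp
floor), signature-proportional pool depths with multiplicative
lognormal noise (coverage is positive and heavy-tailed; additive
Gaussian would produce negative depths) and optional dropout, chimeric
contamination (replacing ⌈fraction·n⌉ contigs with donor contigs),
marker-hit tables with planted duplications, and multinomial read
allocation across genomes and their features with configurable
perfect-match and bad-quality shares.

It does **not** emulate: repeat-induced co-assembly and collapsed
repeats, GC-dependent sequencing bias, platform error models and
quality profiles, chimeric *contigs* (only chimeric clusters),
conserved inter-genus regions, or reference databases with incomplete
species representation. Passing tests therefore demonstrate the
correctness and calibration of the decision rules under the stated
noise models, not the end-to-end accuracy obtainable on real pooled
sequencing runs, where those unmodeled effects dominate the error
budget.

Default study scale: 12 strains × 200 kb genomes × ~40 contigs over 6
combinatorial pools for deconvolution; 20 clean + 5 contaminated
drafts (8 × 5 kb contigs, 30% contamination, donor 30 GC points away)
over 50 seeds for chimera detection; 10^5 reads at abundances
(0.4, 0.3, 0.2, 0.1) for profiling. These sizes run in minutes on one
CPU while preserving the geometry of a real experiment (the real
design sequenced ~30 strains per assembly pool; 12 × 200 kb keeps the
same pools-to-strains ratio at desk scale).

## Numerical choices

* Pearson and Spearman are delegated to scipy.stats; zero-variance
  inputs raise a dedicated error instead of returning NaN. The test
  suite checks both against independent direct-sum / rank-and-correlate
  implementations to 1e−9.
* Nxx is the standard descending-cumulative-sum definition: the largest
  L such that contigs ≥ L cumulate to ≥ f of the total length.
* Assignment ties use an absolute epsilon of 1e−12 on r.
* Degenerate pairs inside the tetranucleotide test (a homopolymer
  contig has a constant frequency vector) are excluded from the mean
  rather than raised, mirroring the no-evidence convention.
* All randomness flows through `numpy.random.default_rng` seeds;
  every generator is reproducible and seed-sensitive.

## Known limitations

* The deconvolution is single-pass: no EM reassignment, no iterative
  abundance re-estimation, no recovery of the unassigned fraction.
* Purity evaluation trusts the upstream genus annotation contract
  (≥ 90% identity over ≥ 100 nt alignments) and does not recompute it.
* The profiler consumes mapped-read tables; alignment, host-read
  subtraction and eukaryote gene prediction are out of scope.
* With P = 6 combinatorial pools the correlation is computed on six
  points; at σ ≳ 0.5 lognormal noise most contigs fall below the 0.95
  cutoff, which is the designed behaviour (purity over completeness)
  but means noisy experiments need more pools or deeper pool
  sequencing.
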