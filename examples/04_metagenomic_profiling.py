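"""Profile a metagenomic sample against a reference genome catalog.

Simulates 10^5 mapped reads from four reference genomes at known
relative abundances, then runs the full profiling chain: quality
filter, informative-feature masking, per-genome coverage metrics,
presence calling and species deduplication.
"""

from combipool import profile_sample, simulate_annotations, simulate_read_profiles

annotations = simulate_annotations(4, n_cds=50, seed=7)
true_abundances = [0.4, 0.3, 0.2, 0.1]
reads, truth = simulate_read_profiles(
    annotations, true_abundances, n_reads=100_000,
    perfect_fraction=0.9, bad_quality_fraction=0.05, seed=7,
)

profiles, calls, total_good = profile_sample(reads, annotations)

print(f"good-quality reads (mean Q >= 20): {total_good}")
print(f"{'genome':10s} {'reads':>7s} {'CDS%':>6s} {'seq%':>6s} "
      f"{'depth':>6s} {'perfect%':>8s} {'present':>7s} {'abund':>6s} {'truth':>6s}")
for p, c in zip(profiles, calls):
    print(f"{p.genome_id:10s} {p.n_reads:7d} {p.pct_cds_covered:6.1f} "
          f"{p.pct_sequence_covered:6.1f} {p.mean_coverage:6.2f} "
          f"{p.pct_perfect_positions:8.1f} {str(c.present):>7s} "
          f"{c.relative_abundance:6.3f} "
          f"{truth.genome_abundance[p.genome_id]:6.3f}")

print("\nCDS% is the breadth over coding regions, depth the mean fold "
      "coverage, perfect% the covered positions supported by at least one "
      "mismatch-free read (high values = the sample strain is near-identical "
      "to the reference). Estimated abundances track the simulated truth.")
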