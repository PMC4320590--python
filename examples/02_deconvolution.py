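"""Recover per-strain genome drafts from pooled contig coverage.

Simulates one assembly pool of 12 strains (200 kb each, ~40 contigs)
with lognormal depth noise over 6 combinatorial pools, then assigns
every contig to the strain whose presence signature its coverage vector
correlates with best (Pearson r >= 0.95).
"""

from combipool import UNASSIGNED, deconvolve_pool, simulate_pool_experiment

clusters_truth, signatures, matrix, truth = simulate_pool_experiment(
    n_strains=12, genome_length=200_000, noise_sigma=0.3, seed=42
)

clusters, unassigned, assignments = deconvolve_pool(matrix, signatures)

assigned = [a for a in assignments if a.assigned_strain != UNASSIGNED]
correct = sum(
    a.assigned_strain == truth.contig_to_strain[a.contig_id] for a in assigned
)
print(f"contigs: {len(assignments)}")
print(f"assigned at r >= 0.95: {len(assigned)} "
      f"({len(assigned) / len(assignments) * 100:.1f}%)")
print(f"of which correctly attributed: {correct} "
      f"({correct / len(assigned) * 100:.1f}%)")
print(f"unassigned (left for manual curation): {unassigned.count}, "
      f"{unassigned.total_length / 1000:.0f} kb")
print("\nper-strain cluster sizes (a draft genome each):")
for c in sorted(clusters, key=lambda c: c.strain_id)[:5]:
    print(f"  {c.strain_id}: {len(c.contig_ids)} contigs, "
          f"{c.total_length / 1000:.0f} kb")
print("  ...")
print("\nUnder noise the 0.95 cutoff trades completeness for purity: "
      "contigs that fall below it stay unassigned instead of risking a "
      "chimeric draft.")
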