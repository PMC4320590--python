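"""Read filtering, feature masking, profiles and presence calls."""

import numpy as np
import pandas as pd
import pytest

from combipool import (
    Feature,
    GenomeAnnotation,
    GenomeProfile,
    call_presence,
    compute_genome_profile,
    dedup_species,
    filter_reads_by_quality,
    mask_uninformative_features,
    prefilter_genomes,
    profile_sample,
    relative_abundance,
    select_candidate_genomes,
    simulate_annotations,
    simulate_read_profiles,
)
from combipool.profiler import READ_COLUMNS, fragment_genome, is_mobile_element


def reads_df(rows):
    return pd.DataFrame(rows, columns=READ_COLUMNS)


def read(rid, q=30.0, genome="g", feature="f1", mm=0, pos=0):
    return (rid, q, genome, feature, mm, pos)


class TestQualityFilter:
    def test_strictly_below_threshold_is_discarded(self):
        df = reads_df([read("a", 19.9), read("b", 20.0), read("c", 35.0)])
        good, n_bad = filter_reads_by_quality(df)
        assert list(good["read_id"]) == ["b", "c"] and n_bad == 1

    def test_empty_input(self):
        good, n_bad = filter_reads_by_quality(reads_df([]))
        assert len(good) == 0 and n_bad == 0


class TestFeatureMasking:
    def test_mobile_element_keywords(self):
        assert is_mobile_element("putative transposase")
        assert is_mobile_element("Integrase, catalytic domain")
        assert is_mobile_element("IS element protein")
        assert is_mobile_element("prophage repressor")
        assert not is_mobile_element("hypothetical protein")
        assert not is_mobile_element("histidine kinase")  # no IS-token hit
        assert not is_mobile_element("ISoleucine-ish label")

    def test_masking_drops_noncoding_and_mobile(self):
        ann = GenomeAnnotation(
            "g", "sp",
            [
                Feature("f1", 0, 300, "CDS", "hypothetical protein"),
                Feature("f2", 300, 400, "tRNA", ""),
                Feature("f3", 400, 500, "rRNA", ""),
                Feature("f4", 500, 600, "intergenic", ""),
                Feature("f5", 600, 900, "CDS", "phage tail fiber"),
            ],
        )
        kept = [f.feature_id for f in mask_uninformative_features(ann)]
        assert kept == ["f1"]

    def test_unannotated_genome_is_fragmented_with_remainder(self):
        ann = GenomeAnnotation("g", "sp", [], annotated=False, genome_length=3500)
        frags = mask_uninformative_features(ann)
        assert [f.length for f in frags] == [1000, 1000, 1000, 500]
        assert fragment_genome(3500)[-1].end == 3500


def uniform_reads(feature, start, end, depth, read_length=50, q=30.0, mm=0,
                  genome="g"):
    """Reads tiling [start, end) at exactly ``depth``-fold coverage."""
    rows = []
    rid = 0
    for pos in range(start, end, read_length):
        for _ in range(depth):
            rows.append((f"{feature}_{rid}", q, genome, feature, mm, pos))
            rid += 1
    return rows


class TestGenomeProfile:
    FEATS = [Feature("f1", 0, 300, "CDS"), Feature("f2", 300, 1000, "CDS")]

    def test_worked_example_breadth_and_depth(self):
        # CDS1 (300 nt) fully covered at uniform 10x, CDS2 (700 nt) untouched
        df = reads_df(uniform_reads("f1", 0, 300, 10))
        p = compute_genome_profile(df, self.FEATS, total_good_reads=1000)
        assert p.pct_cds_covered == pytest.approx(50.0)
        assert p.pct_sequence_covered == pytest.approx(30.0)
        assert p.mean_coverage == pytest.approx(3.0)
        assert p.n_reads == 60
        assert p.pct_mapped_reads == pytest.approx(6.0)

    def test_perfect_position_fraction(self):
        # 300 covered positions; only the first 200 touched by 0-mismatch reads
        rows = uniform_reads("f1", 0, 200, 1, mm=0)
        rows += uniform_reads("f1", 200, 300, 1, mm=2)
        p = compute_genome_profile(reads_df(rows), self.FEATS, 1000)
        assert p.pct_perfect_positions == pytest.approx(200 / 300 * 100, abs=0.05)

    def test_zero_reads_gives_zero_metrics(self):
        p = compute_genome_profile(reads_df([]), self.FEATS, 1000)
        assert (p.n_reads, p.pct_cds_covered, p.mean_coverage,
                p.pct_perfect_positions) == (0, 0.0, 0.0, 0.0)

    def test_reads_outside_informative_features_are_ignored(self):
        rows = uniform_reads("f1", 0, 300, 1) + [read("x", feature="ghost")]
        p = compute_genome_profile(reads_df(rows), self.FEATS, 1000)
        assert p.n_reads == 6


def profile(n_reads=1000, n_cds=100, pct=90.0, species="sp", gid="g1"):
    return GenomeProfile(
        genome_id=gid, species=species, n_reads=n_reads, n_cds=n_cds,
        cumulated_cds_length=n_cds * 900, pct_cds_covered=pct,
        pct_sequence_covered=pct, mean_coverage=1.0, pct_mapped_reads=1.0,
        pct_perfect_positions=100.0,
    )


class TestFiltersAndPresence:
    def test_candidate_selection_at_20_percent_features(self):
        kept = select_candidate_genomes(
            [profile(pct=15.0, gid="a"), profile(pct=25.0, gid="b"),
             profile(pct=19.0, gid="c")]
        )
        assert [p.genome_id for p in kept] == ["b"]

    @pytest.mark.parametrize(
        "n_reads,pct,kept",
        [(699, 25.0, False), (700, 25.0, True), (10_000, 19.9, False),
         (700, 20.0, True)],
    )
    def test_prefilter_boundaries(self, n_reads, pct, kept):
        out = prefilter_genomes([profile(n_reads=n_reads, pct=pct)])
        assert bool(out) is kept

    @pytest.mark.parametrize(
        "avg,pct,present",
        [
            (a, p, (a >= 10 and p > 80) or (2 <= a < 10 and p > 70))
            for a in (1.5, 2, 5, 10, 12)
            for p in (65, 70, 70.1, 80, 80.1, 85)
        ],
    )
    def test_presence_truth_table_over_rule_boundaries(self, avg, pct, present):
        # avg = n_reads / n_cds built exactly from integer pairs
        n_cds = 1000
        p = profile(n_reads=int(avg * n_cds), n_cds=n_cds, pct=pct)
        assert p.avg_reads_per_cds == pytest.approx(avg)
        call = call_presence(p, total_good_reads=10 ** 6)
        assert call.present is present

    def test_dedup_keeps_highest_breadth_then_smallest_id(self):
        a = profile(pct=45.0, gid="gB")
        b = profile(pct=60.0, gid="gA")
        c = profile(pct=60.0, gid="gC", species="other")
        d = profile(pct=60.0, gid="gB2", species="other")
        kept = dedup_species([a, b, c, d])
        assert {p.genome_id for p in kept} == {"gA", "gB2"}

    def test_relative_abundance(self):
        assert relative_abundance(profile(n_reads=100), 1000) == pytest.approx(0.1)
        assert relative_abundance(profile(n_reads=0), 1000) == 0.0
        import combipool

        with pytest.raises(combipool.SchemaError):
            relative_abundance(profile(), 0)


class TestFullChain:
    def test_abundance_recovery_and_determinism(self):
        anns = simulate_annotations(3, seed=2)
        reads, truth = simulate_read_profiles(
            anns, [0.5, 0.3, 0.2], 30_000, seed=2
        )
        profiles, calls, total = profile_sample(reads, anns)
        assert total == 30_000
        est = {c.genome_id: c.relative_abundance for c in calls}
        for gid, true_ab in truth.genome_abundance.items():
            se = np.sqrt(true_ab * (1 - true_ab) / 30_000)
            assert abs(est[gid] - true_ab) <= 3 * se
        # byte-identical on rerun: the chain is deterministic
        profiles2, calls2, _ = profile_sample(reads.copy(), anns)
        assert [vars(p) for p in profiles2] == [vars(p) for p in profiles]
        assert [vars(c) for c in calls2] == [vars(c) for c in calls]

    def test_all_perfect_reads_give_100_percent_perfect_positions(self):
        anns = simulate_annotations(2, seed=3)
        reads, _ = simulate_read_profiles(
            anns, [0.6, 0.4], 20_000, perfect_fraction=1.0, seed=3
        )
        profiles, _, _ = profile_sample(reads, anns)
        for p in profiles:
            assert p.pct_perfect_positions == pytest.approx(100.0)
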