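"""Assembly metrics, chimera tests, tiering and cluster purity."""

import numpy as np
import pandas as pd
import pytest

from combipool import (
    Contig,
    DraftCluster,
    SchemaError,
    ThresholdConfig,
    UndefinedCorrelationError,
    classify_draft,
    cluster_purity,
    compute_assembly_metrics,
    compute_nxx,
    essential_gene_completeness,
    marker_redundancy,
    spearman_rho,
    tetra_homogeneity,
    tetranucleotide_vector,
)
from combipool.qc import AssemblyMetrics, MARKER_COLUMNS, TAX_COLUMNS
from combipool.simulate import CompositionModel, generate_genome
from oracles import nxx_oracle, spearman_oracle


def hits(rows):
    return pd.DataFrame(rows, columns=MARKER_COLUMNS)


class TestNxx:
    @pytest.mark.parametrize(
        "lengths,f,expected",
        [((7, 4, 3, 2), 0.5, 4), ((7, 4, 3, 2), 0.9, 2), ((42,), 0.5, 42),
         ((42,), 0.9, 42)],
    )
    def test_worked_examples(self, lengths, f, expected):
        assert compute_nxx(lengths, f) == expected

    def test_matches_enumeration_oracle_on_random_instances(self, rng):
        for _ in range(300):
            n = int(rng.integers(1, 30))
            lengths = rng.integers(1, 10_000, size=n).tolist()
            f = float(rng.uniform(0.05, 0.95))
            assert compute_nxx(lengths, f) == nxx_oracle(lengths, f)

    def test_empty_input_is_an_error(self):
        with pytest.raises(SchemaError):
            compute_nxx([], 0.5)


class TestAssemblyMetrics:
    def test_worked_example_kilobases(self):
        m = compute_assembly_metrics([7000, 4000, 3000, 2000])
        assert (m.contig_N50, m.contig_N90) == (4000, 2000)
        assert m.mean_contig_length == 4000
        assert m.scaffold_N50 == 4000  # falls back to contig N50

    def test_coverage_fraction_is_strictly_greater_than_five(self):
        m10 = compute_assembly_metrics([100], per_base_depths=np.full(100, 10.0))
        m5 = compute_assembly_metrics([100], per_base_depths=np.full(100, 5.0))
        assert m10.frac_bases_gt5x == 1.0
        assert m5.frac_bases_gt5x == 0.0

    def test_absent_depths_give_none(self):
        assert compute_assembly_metrics([100]).frac_bases_gt5x is None


class TestEssentialGenes:
    def test_full_catalog_passes(self):
        t = hits([(f"e{i}", "c1", 80.0, 80.0) for i in range(99)])
        frac, ok = essential_gene_completeness(t)
        assert frac == 1.0 and ok

    def test_89_of_99_fails_the_90_percent_rule(self):
        t = hits([(f"e{i}", "c1", 80.0, 80.0) for i in range(89)])
        frac, ok = essential_gene_completeness(t)
        assert frac == pytest.approx(89 / 99) and not ok

    def test_weak_hits_below_50_50_are_ignored(self):
        t = hits(
            [(f"e{i}", "c1", 80.0, 80.0) for i in range(89)]
            + [("e98", "c1", 40.0, 80.0), ("e99", "c1", 80.0, 49.0)]
        )
        frac, ok = essential_gene_completeness(t)
        assert frac == pytest.approx(89 / 99) and not ok


class TestTetranucleotides:
    def test_homopolymer(self):
        v = tetranucleotide_vector("AAAAAA")
        assert v[0] == pytest.approx(3 / 6)
        assert v.sum() == pytest.approx(3 / 6)

    def test_acgt_repeat_enumerated_windows(self):
        from combipool.qc import TETRANUCLEOTIDES

        v = tetranucleotide_vector("ACGTACGT")
        idx = {t: i for i, t in enumerate(TETRANUCLEOTIDES)}
        assert v[idx["ACGT"]] == pytest.approx(2 / 8)
        for w in ("CGTA", "GTAC", "TACG"):
            assert v[idx[w]] == pytest.approx(1 / 8)
        assert v.sum() == pytest.approx(5 / 8)

    def test_too_short_errors(self):
        with pytest.raises(SchemaError):
            tetranucleotide_vector("ACG")

    def test_ambiguous_windows_dropped_but_length_denominator_kept(self):
        v = tetranucleotide_vector("ACGTNACGT")
        # windows touching N are dropped: ACGT appears twice over len 9
        assert v.sum() == pytest.approx(2 / 9)


class TestSpearman:
    def test_monotone_and_antitone(self):
        x = [1.0, 2.0, 3.0, 5.0]
        assert spearman_rho(x, [2.0, 4.0, 6.0, 10.0]) == pytest.approx(1.0)
        assert spearman_rho(x, [10.0, 6.0, 4.0, 2.0]) == pytest.approx(-1.0)

    def test_tied_case_matches_average_rank_oracle(self):
        xs, ys = [1, 2, 2, 3], [1, 2, 3, 3]
        # frozen from the rank-and-correlate oracle
        assert spearman_rho(xs, ys) == pytest.approx(0.8333333333333335, abs=1e-12)
        assert spearman_rho(xs, ys) == pytest.approx(
            spearman_oracle(xs, ys), abs=1e-12
        )

    def test_random_tied_data_agrees_with_oracle(self, rng):
        for _ in range(200):
            n = int(rng.integers(3, 15))
            x = rng.integers(0, 5, size=n).tolist()
            y = rng.integers(0, 5, size=n).tolist()
            if len(set(x)) == 1 or len(set(y)) == 1:
                continue
            assert spearman_rho(x, y) == pytest.approx(
                spearman_oracle(x, y), abs=1e-9
            )

    def test_constant_input_errors(self):
        with pytest.raises(UndefinedCorrelationError):
            spearman_rho([1, 1, 1], [1, 2, 3])


def _draft(model, n, length, seed):
    rng = np.random.default_rng(seed)
    return [
        Contig(f"c{i}", 0, length,
               generate_genome(length, model, int(rng.integers(2 ** 31))))
        for i in range(n)
    ]


class TestTetraHomogeneity:
    def test_identical_contigs_are_perfectly_homogeneous(self):
        seq = generate_genome(5000, CompositionModel.gc_bias(0.5), seed=1)
        contigs = [Contig(f"c{i}", 0, 5000, seq) for i in range(5)]
        rho, flagged = tetra_homogeneity(contigs)
        assert rho == pytest.approx(1.0) and not flagged

    def test_single_source_draft_is_homogeneous(self):
        contigs = _draft(CompositionModel.random_markov(3), 8, 5000, seed=3)
        rho, flagged = tetra_homogeneity(contigs)
        assert rho > 0.6 and not flagged

    def test_gc_split_draft_is_flagged(self):
        low = _draft(CompositionModel.gc_bias(0.30), 4, 5000, seed=4)
        high = _draft(CompositionModel.gc_bias(0.70), 4, 5000, seed=5)
        rho, flagged = tetra_homogeneity(low + high)
        assert rho < 0.6 and flagged

    def test_order_invariance_and_short_contig_exclusion(self):
        contigs = _draft(CompositionModel.gc_bias(0.45), 6, 2000, seed=6)
        rho1, _ = tetra_homogeneity(contigs)
        rho2, _ = tetra_homogeneity(contigs[::-1])
        assert rho1 == pytest.approx(rho2)
        short = [Contig("tiny", 0, 200, "ACGT" * 50)]
        rho3, _ = tetra_homogeneity(contigs + short)
        assert rho3 == pytest.approx(rho1)  # <1 kb contigs are ignored

    def test_fewer_than_two_eligible_contigs_is_not_evidence(self):
        one = _draft(CompositionModel.gc_bias(0.5), 1, 2000, seed=7)
        assert tetra_homogeneity(one) == (None, False)


class TestMarkerRedundancy:
    def test_single_copy_everywhere_is_clean(self):
        t = hits([(f"m{i}", "c1", 80.0, 80.0) for i in range(40)])
        assert marker_redundancy(t) == (0, False)

    def test_three_duplicated_markers_is_chimeric(self):
        rows = [(f"m{i}", "c1", 80.0, 80.0) for i in range(40)]
        rows += [("m1", "c9", 80.0, 80.0), ("m2", "c9", 80.0, 80.0),
                 ("m3", "c9", 80.0, 80.0)]
        assert marker_redundancy(hits(rows)) == (3, True)

    def test_two_duplicated_markers_is_not_chimeric(self):
        rows = [(f"m{i}", "c1", 80.0, 80.0) for i in range(40)]
        rows += [("m1", "c9", 80.0, 80.0), ("m2", "c9", 80.0, 80.0)]
        assert marker_redundancy(hits(rows)) == (2, False)

    def test_weak_duplicate_hits_do_not_count(self):
        rows = [(f"m{i}", "c1", 80.0, 80.0) for i in range(40)]
        rows += [(f"m{i}", "c9", 40.0, 80.0) for i in range(5)]
        assert marker_redundancy(hits(rows)) == (0, False)


def metrics(total=2_000_000, n50=10_000, n90=1_000, mean=8_000,
            s50=30_000, frac=0.95):
    n = max(1, round(total / mean))
    return AssemblyMetrics(
        n_contigs=n, total_length=total, contig_N50=n50, contig_N90=n90,
        mean_contig_length=total / n if mean else 0, scaffold_N50=s50,
        frac_bases_gt5x=frac,
    )


class TestClassifyDraft:
    def test_small_draft_is_excluded(self):
        tier, _ = classify_draft(
            metrics(total=800_000), (1.0, True), (0.9, False), (0, False)
        )
        assert tier == "excluded"

    def test_all_criteria_pass_is_high_quality(self):
        tier, hmp = classify_draft(
            metrics(), (0.95, True), (0.9, False), (0, False)
        )
        assert tier == "high_quality" and hmp.all_pass

    def test_incomplete_essential_set_is_standard(self):
        tier, _ = classify_draft(
            metrics(total=1_500_000), (0.5, False), (0.9, False), (1, False)
        )
        assert tier == "standard"

    def test_contiguity_failure_is_near_complete(self):
        tier, hmp = classify_draft(
            metrics(n50=2_000), (0.95, True), (0.9, False), (0, False)
        )
        assert tier == "near_complete" and not hmp.contig_n50_ok

    def test_chimera_always_excludes(self):
        for tetra_flag, marker_flag in [(True, False), (False, True), (True, True)]:
            tier, _ = classify_draft(
                metrics(), (1.0, True), (0.4, tetra_flag), (5, marker_flag)
            )
            assert tier == "excluded"


class TestClusterPurity:
    def _tax(self, rows):
        return pd.DataFrame(rows, columns=TAX_COLUMNS)

    def test_worked_example(self):
        lengths = {"x": 500_000, "y": 50_000, "u": 50_000}
        cluster = DraftCluster("s", ["x", "y", "u"], 600_000)
        tax = self._tax([("x", "GenusX", 500_000), ("y", "GenusY", 50_000)])
        dom, ref = cluster_purity(cluster, tax, lengths)
        assert dom == pytest.approx(91.7, abs=0.05)
        assert ref == pytest.approx(83.3, abs=0.05)

    def test_pure_cluster_is_100_100(self):
        lengths = {"a": 300_000, "b": 300_000}
        cluster = DraftCluster("s", ["a", "b"], 600_000)
        tax = self._tax([("a", "GenusX", 300_000), ("b", "GenusX", 300_000)])
        assert cluster_purity(cluster, tax, lengths) == (100.0, 100.0)

    def test_small_cluster_is_skipped(self):
        lengths = {"a": 400_000}
        cluster = DraftCluster("s", ["a"], 400_000)
        assert cluster_purity(cluster, self._tax([]), lengths) is None

    def test_explicit_unassigned_rows_count_toward_dominant(self):
        from combipool import UNASSIGNED

        lengths = {"a": 400_000, "b": 200_000}
        cluster = DraftCluster("s", ["a", "b"], 600_000)
        tax = self._tax([("a", "GenusX", 400_000), ("b", UNASSIGNED, 200_000)])
        dom, ref = cluster_purity(cluster, tax, lengths)
        assert dom == pytest.approx(100.0)
        assert ref == pytest.approx(400_000 / 600_000 * 100)
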