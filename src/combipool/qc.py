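"""Draft-genome quality evaluation.

Drafts reconstructed by pooled-sequencing deconvolution are scored with:

* the six HMP draft-submission criteria (contig N90 >= 500 bp, >= 90% of
  the 99 bacterial essential genes present, >= 90% of assembly bases at
  more than 5-fold coverage, contig N50 >= 5 kb, scaffold N50 >= 20 kb,
  mean contig length >= 5 kb);
* two chimera tests that catch mis-assigned contigs: tetranucleotide
  homogeneity (mean pairwise Spearman rho of per-contig 4-mer frequency
  vectors below 0.6 flags contamination) and single-copy-marker
  redundancy (3+ duplicated markers out of 40 flags a chimera);
* length-weighted taxonomic purity of a cluster against reference
  genus annotations.

Drafts are then tiered: high_quality (all criteria), near_complete
(essential genes + chimera tests pass, some assembly-contiguity
criterion fails), standard (chimera tests pass, essential-gene set
incomplete), excluded (< 1 Mb cumulative contigs or a chimera test
fails).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, product
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import ThresholdConfig
from .covmatrix import Contig
from .deconvolve import DraftCluster, UNASSIGNED
from .errors import SchemaError, UndefinedCorrelationError

MARKER_COLUMNS = ["marker_id", "contig_id", "identity_pct", "coverage_pct"]
TAX_COLUMNS = ["contig_id", "genus", "aligned_length"]

_BASE_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i
    _BASE_CODE[_b + 32] = _i  # lowercase

TETRANUCLEOTIDES = ["".join(p) for p in product("ACGT", repeat=4)]


@dataclass
class AssemblyMetrics:
    n_contigs: int
    total_length: int
    contig_N50: int
    contig_N90: int
    mean_contig_length: float
    scaffold_N50: int
    frac_bases_gt5x: float | None  # None when per-base depths are absent


@dataclass(frozen=True)
class MarkerHit:
    marker_id: str
    contig_id: str
    identity_pct: float
    coverage_pct: float


@dataclass
class HMPCriteria:
    """The six HMP submission booleans, in the published order."""

    n90_ok: bool
    essential_ok: bool
    coverage_ok: bool
    contig_n50_ok: bool
    scaffold_n50_ok: bool
    mean_contig_ok: bool

    @property
    def all_pass(self) -> bool:
        return all(
            (self.n90_ok, self.essential_ok, self.coverage_ok,
             self.contig_n50_ok, self.scaffold_n50_ok, self.mean_contig_ok)
        )


@dataclass
class QualityReport:
    strain_id: str
    metrics: AssemblyMetrics
    hmp: HMPCriteria
    essential_fraction: float
    tetra_mean_rho: float | None  # None = N/A (fewer than 2 eligible contigs)
    tetra_contaminated: bool
    n_redundant_markers: int
    marker_chimeric: bool
    tier: str  # high_quality | near_complete | standard | excluded


def compute_nxx(lengths: Sequence[int], f: float) -> int:
    """Standard Nxx: largest L with contigs >= L cumulating to >= f of total.

    Sort descending and walk the cumulative sum; N50 is ``f=0.5``, N90 is
    ``f=0.9``.
    """
    if not 0.0 < f < 1.0:
        raise SchemaError(f"fraction must be in (0,1), got {f}")
    lens = sorted(lengths, reverse=True)
    if not lens:
        raise SchemaError("compute_nxx: empty length list")
    if min(lens) <= 0:
        raise SchemaError("compute_nxx: lengths must be positive")
    target = f * sum(lens)
    acc = 0
    for L in lens:
        acc += L
        if acc >= target:
            return L
    return lens[-1]  # unreachable; f < 1 guarantees early return


def compute_assembly_metrics(
    contig_lengths: Sequence[int],
    scaffold_lengths: Sequence[int] | None = None,
    per_base_depths: np.ndarray | None = None,
) -> AssemblyMetrics:
    """Assembly statistics for one draft.

    ``per_base_depths`` is a flat array of fold coverage over every
    assembled base (order irrelevant); the >5x fraction uses a strict
    inequality.  ``scaffold_N50`` falls back to the contig N50 when no
    scaffolds exist.
    """
    if not contig_lengths:
        raise SchemaError("assembly metrics need at least one contig")
    total = int(sum(contig_lengths))
    n50 = compute_nxx(contig_lengths, 0.5)
    n90 = compute_nxx(contig_lengths, 0.9)
    s50 = compute_nxx(scaffold_lengths, 0.5) if scaffold_lengths else n50
    frac = None
    if per_base_depths is not None:
        d = np.asarray(per_base_depths, dtype=float)
        frac = float(np.mean(d > 5.0)) if d.size else 0.0
    return AssemblyMetrics(
        n_contigs=len(contig_lengths),
        total_length=total,
        contig_N50=n50,
        contig_N90=n90,
        mean_contig_length=total / len(contig_lengths),
        scaffold_N50=s50,
        frac_bases_gt5x=frac,
    )


def _filter_marker_hits(hits: pd.DataFrame, cfg: ThresholdConfig) -> pd.DataFrame:
    missing = set(MARKER_COLUMNS) - set(hits.columns)
    if missing:
        raise SchemaError(f"marker table missing columns {sorted(missing)}")
    keep = (hits["identity_pct"] >= cfg.marker_identity_min) & (
        hits["coverage_pct"] >= cfg.marker_coverage_min
    )
    return hits[keep]


def essential_gene_completeness(
    hits: pd.DataFrame, cfg: ThresholdConfig | None = None
) -> tuple[float, bool]:
    """Fraction of the 99-gene bacterial essential set recovered.

    Hits below 50% identity or 50% coverage are ignored; the draft passes
    when at least 90% of the catalog (i.e. >= 90 of 99 genes) is found.
    """
    cfg = cfg or ThresholdConfig()
    good = _filter_marker_hits(hits, cfg)
    fraction = good["marker_id"].nunique() / cfg.n_essential_genes
    return fraction, fraction >= cfg.hmp_essential_min


def marker_redundancy(
    hits: pd.DataFrame, cfg: ThresholdConfig | None = None
) -> tuple[int, bool]:
    """Duplicated single-copy phylogenetic markers.

    These 40 protein families occur exactly once in a normal bacterial
    genome, so a marker found twice in one draft means two genomes were
    merged.  Three or more duplicated markers call the draft chimeric.
    """
    cfg = cfg or ThresholdConfig()
    good = _filter_marker_hits(hits, cfg)
    counts = good.groupby("marker_id").size()
    n_redundant = int((counts >= 2).sum())
    return n_redundant, n_redundant >= cfg.marker_redundancy_min


def tetranucleotide_vector(seq: str) -> np.ndarray:
    """4-mer frequency vector of a sequence.

    Counts every overlapping 4-base window (windows containing non-ACGT
    characters are dropped) and divides by the sequence length, giving a
    256-dimensional compositional signature.  Counting is on the given
    strand without reverse-complement collapsing: strand is fixed by the
    assembly.
    """
    if len(seq) < 4:
        raise SchemaError("sequence shorter than 4: no tetranucleotide window")
    codes = _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    k = codes.size - 3
    kmers = codes[0:k] * 64 + codes[1:k + 1] * 16 + codes[2:k + 2] * 4 + codes[3:k + 3]
    valid = (
        (codes[0:k] >= 0) & (codes[1:k + 1] >= 0)
        & (codes[2:k + 2] >= 0) & (codes[3:k + 3] >= 0)
    )
    counts = np.bincount(kmers[valid], minlength=256)
    return counts / len(seq)


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation with average ranks for ties."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise SchemaError("spearman_rho needs two equal-length vectors (n >= 2)")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero rank variance")
    return float(stats.spearmanr(x, y).statistic)


def tetra_homogeneity(
    contigs: Iterable[Contig], cfg: ThresholdConfig | None = None
) -> tuple[float | None, bool]:
    """Compositional homogeneity of a draft's contigs.

    Mean of all pairwise Spearman rho between per-contig tetranucleotide
    vectors; a genome's contigs share a composition, so a low mean
    (< ``rho_min``, default 0.6) indicates contigs from another organism.
    Only contigs >= 1 kb with sequence enter (short contigs give noisy
    rank correlations).  Fewer than 2 eligible contigs -> (None, False):
    absence of evidence is not chimerism.
    """
    cfg = cfg or ThresholdConfig()
    eligible = [
        c for c in contigs
        if c.sequence is not None and c.length >= cfg.tetra_min_contig_len
    ]
    if len(eligible) < 2:
        return None, False
    vectors = [tetranucleotide_vector(c.sequence) for c in eligible]
    rhos = []
    for a, b in combinations(vectors, 2):
        try:
            rhos.append(spearman_rho(a, b))
        except UndefinedCorrelationError:
            continue  # degenerate pair (e.g. homopolymer contig): no evidence
    if not rhos:
        return None, False
    mean_rho = float(np.mean(rhos))
    return mean_rho, mean_rho < cfg.rho_min


def classify_draft(
    metrics: AssemblyMetrics,
    essential_result: tuple[float, bool],
    tetra_result: tuple[float | None, bool],
    redundancy_result: tuple[int, bool],
    cfg: ThresholdConfig | None = None,
) -> tuple[str, HMPCriteria]:
    """Tier a draft from its component results.

    excluded      — cumulative contig size < 1 Mb, or either chimera test
                    fails (tetranucleotide heterogeneity or marker
                    redundancy): unusable or mis-assigned.
    standard      — chimera tests pass but the essential-gene set is
                    incomplete: usable with caution.
    near_complete — chimera tests and essential genes pass but at least one
                    assembly-contiguity HMP criterion fails.
    high_quality  — all six HMP criteria and both chimera tests pass.

    A coverage fraction of None (no per-base depths supplied) passes with
    a warning semantics analogous to the N/A tetranucleotide case.
    """
    cfg = cfg or ThresholdConfig()
    essential_fraction, essential_ok = essential_result
    _, tetra_flag = tetra_result
    _, marker_flag = redundancy_result
    coverage_ok = (
        metrics.frac_bases_gt5x is None
        or metrics.frac_bases_gt5x >= cfg.hmp_frac_gt5x_min
    )
    hmp = HMPCriteria(
        n90_ok=metrics.contig_N90 >= cfg.hmp_n90_min,
        essential_ok=essential_ok,
        coverage_ok=coverage_ok,
        contig_n50_ok=metrics.contig_N50 >= cfg.hmp_contig_n50_min,
        scaffold_n50_ok=metrics.scaffold_N50 >= cfg.hmp_scaffold_n50_min,
        mean_contig_ok=metrics.mean_contig_length >= cfg.hmp_mean_contig_min,
    )
    if metrics.total_length < cfg.min_submit_size or tetra_flag or marker_flag:
        return "excluded", hmp
    if not essential_ok:
        return "standard", hmp
    if hmp.all_pass:
        return "high_quality", hmp
    return "near_complete", hmp


def evaluate_draft(
    strain_id: str,
    contigs: list[Contig],
    essential_hits: pd.DataFrame,
    marker_hits: pd.DataFrame,
    scaffold_lengths: Sequence[int] | None = None,
    per_base_depths: np.ndarray | None = None,
    cfg: ThresholdConfig | None = None,
) -> QualityReport:
    """Run every QC component on one draft and tier it."""
    cfg = cfg or ThresholdConfig()
    metrics = compute_assembly_metrics(
        [c.length for c in contigs], scaffold_lengths, per_base_depths
    )
    essential = essential_gene_completeness(essential_hits, cfg)
    tetra = tetra_homogeneity(contigs, cfg)
    redundancy = marker_redundancy(marker_hits, cfg)
    tier, hmp = classify_draft(metrics, essential, tetra, redundancy, cfg)
    return QualityReport(
        strain_id=strain_id,
        metrics=metrics,
        hmp=hmp,
        essential_fraction=essential[0],
        tetra_mean_rho=tetra[0],
        tetra_contaminated=tetra[1],
        n_redundant_markers=redundancy[0],
        marker_chimeric=redundancy[1],
        tier=tier,
    )


def cluster_purity(
    cluster: DraftCluster,
    tax_hits: pd.DataFrame,
    contig_lengths: dict[str, int],
    cfg: ThresholdConfig | None = None,
) -> tuple[float, float] | None:
    """Length-weighted taxonomic purity of a deconvolved cluster.

    ``tax_hits`` columns: contig_id, genus (or UNASSIGNED), aligned_length;
    the genus calls come from reference alignments (>= 90% identity over
    >= 100 nt, an upstream contract).  The dominant genus is the one with
    maximal mapped length.  Unassigned contigs count toward the dominant
    genus (they carry no evidence of mis-assignment), so

    * dominant_genus_pct  = (dominant + unassigned length) / total * 100
    * reference_coverage_pct = dominant length / total * 100

    Clusters under 500 kb are too fragmented to judge: returns None.
    """
    cfg = cfg or ThresholdConfig()
    total = sum(contig_lengths[c] for c in cluster.contig_ids)
    if total < cfg.min_cluster_eval_size:
        return None
    missing = set(TAX_COLUMNS) - set(tax_hits.columns)
    if missing:
        raise SchemaError(f"tax table missing columns {sorted(missing)}")
    in_cluster = tax_hits[tax_hits["contig_id"].isin(cluster.contig_ids)]
    by_genus = in_cluster.groupby("genus")["aligned_length"].sum()
    annotated = set(in_cluster["contig_id"])
    unassigned_len = sum(
        contig_lengths[c] for c in cluster.contig_ids if c not in annotated
    )
    unassigned_len += int(by_genus.get(UNASSIGNED, 0))
    real = by_genus.drop(UNASSIGNED, errors="ignore")
    dominant_len = int(real.max()) if len(real) else 0
    dominant_pct = (dominant_len + unassigned_len) / total * 100.0
    ref_cov_pct = dominant_len / total * 100.0
    return dominant_pct, ref_cov_pct
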