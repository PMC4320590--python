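"""Reference-based metagenomic profiling and presence calling.

Given quality-filtered reads mapped against a reference genome catalog,
the profiler reports — per genome — read counts, breadth and depth of
coverage over the informative coding regions, the fraction of
perfectly-matching covered positions, and a presence call.  Regions
unlikely to be strain-diagnostic (intergenic, tRNA, rRNA, and mobile
elements: transposases, integrases, IS elements, phages, plasmids) are
masked before counting; genomes with no annotation are cut into
1000-base fragments that play the role of genes.

Presence of a species requires the reads to be both numerous and evenly
spread: with avg = reads per CDS, a genome is called present when
avg >= 10 and more than 80% of its CDS are covered, or when
2 <= avg < 10 and more than 70% are covered.  After calling, one
reference per species is kept (the one with the highest CDS breadth),
and relative abundance is reads on the genome / total good reads.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ThresholdConfig
from .errors import SchemaError

NO_FEATURE = "NONE"
DEFAULT_READ_LENGTH = 50  # aligned span per read (short-read, single-end)

READ_COLUMNS = [
    "read_id", "mean_quality", "genome_id", "feature_id", "mismatches", "position",
]

MOBILE_KEYWORDS = ("transposase", "integrase", "phage", "prophage", "plasmid")
_IS_TOKEN = re.compile(r"(?<![A-Za-z0-9])IS(?![A-Za-z0-9])", re.IGNORECASE)

UNINFORMATIVE_KINDS = {"intergenic", "tRNA", "rRNA"}


@dataclass(frozen=True)
class Feature:
    feature_id: str
    start: int  # 0-based, half-open
    end: int
    kind: str = "CDS"  # CDS | tRNA | rRNA | intergenic | fragment
    product: str = ""

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise SchemaError(
                f"feature {self.feature_id}: bad interval [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GenomeAnnotation:
    genome_id: str
    species: str
    features: list[Feature]
    annotated: bool = True
    genome_length: int | None = None


@dataclass
class GenomeProfile:
    """Per-reference mapping metrics (one row of the sample profile table)."""

    genome_id: str
    species: str
    n_reads: int
    n_cds: int
    cumulated_cds_length: int
    pct_cds_covered: float
    pct_sequence_covered: float
    mean_coverage: float
    pct_mapped_reads: float
    pct_perfect_positions: float

    @property
    def avg_reads_per_cds(self) -> float:
        return self.n_reads / self.n_cds if self.n_cds else 0.0


@dataclass
class PresenceCall:
    genome_id: str
    species: str
    present: bool
    reason: str
    relative_abundance: float


def filter_reads_by_quality(
    reads: pd.DataFrame, q_min: float = 20.0
) -> tuple[pd.DataFrame, int]:
    """Drop bad-quality reads (mean base quality strictly under ``q_min``)."""
    if "mean_quality" not in reads.columns:
        raise SchemaError("read table missing mean_quality column")
    good = reads[reads["mean_quality"] >= q_min]
    return good, len(reads) - len(good)


def is_mobile_element(product: str) -> bool:
    """Case-insensitive keyword match; 'IS' only as a standalone token."""
    low = product.lower()
    if any(kw in low for kw in MOBILE_KEYWORDS):
        return True
    return bool(_IS_TOKEN.search(product))


def fragment_genome(genome_length: int, fragment_size: int = 1000) -> list[Feature]:
    """Cut an unannotated genome into consecutive fragments.

    The final partial fragment (< ``fragment_size``) is kept; dropping it
    would bias small replicons.
    """
    feats = []
    for i, start in enumerate(range(0, genome_length, fragment_size), start=1):
        end = min(start + fragment_size, genome_length)
        feats.append(Feature(f"frag_{i:05d}", start, end, kind="fragment"))
    return feats


def mask_uninformative_features(ann: GenomeAnnotation) -> list[Feature]:
    """Informative features of a genome: CDS minus mobile elements.

    Intergenic, tRNA and rRNA features are removed, as are CDS whose
    product label names a mobile element.  An unannotated genome yields
    its 1000-base fragments instead.
    """
    if not ann.annotated:
        if ann.genome_length is None:
            raise SchemaError(
                f"unannotated genome {ann.genome_id} needs genome_length"
            )
        return fragment_genome(ann.genome_length)
    kept = []
    for f in ann.features:
        if f.kind in UNINFORMATIVE_KINDS:
            continue
        if f.kind == "CDS" and is_mobile_element(f.product):
            continue
        kept.append(f)
    return kept


def _coverage_arrays(
    reads: pd.DataFrame, features: list[Feature], read_length: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Per-position coverage over the informative-feature union.

    Returns (mask of informative positions, depth per position, perfect-read
    depth per position, total aligned bases within informative positions).
    """
    span = max(f.end for f in features)
    mask = np.zeros(span, dtype=bool)
    for f in features:
        mask[f.start:f.end] = True
    depth = np.zeros(span + read_length + 1, dtype=np.int64)
    perfect = np.zeros(span + read_length + 1, dtype=np.int64)
    pos = reads["position"].to_numpy(dtype=np.int64)
    mm = reads["mismatches"].to_numpy(dtype=np.int64)
    ends = np.minimum(pos + read_length, span)
    np.add.at(depth, pos, 1)
    np.add.at(depth, ends, -1)
    zero = mm == 0
    np.add.at(perfect, pos[zero], 1)
    np.add.at(perfect, ends[zero], -1)
    depth = np.cumsum(depth)[:span]
    perfect = np.cumsum(perfect)[:span]
    aligned = int(depth[mask].sum())
    return mask, depth, perfect, aligned


def compute_genome_profile(
    reads: pd.DataFrame,
    features: list[Feature],
    total_good_reads: int,
    genome_id: str = "",
    species: str = "",
    read_length: int = DEFAULT_READ_LENGTH,
) -> GenomeProfile:
    """Mapping metrics for one genome from its informative-feature reads.

    ``reads`` must already be restricted to this genome; reads whose
    feature_id is not informative are dropped here.  Breadth, depth and
    perfect-match metrics are computed over the union of informative
    feature positions (0-based half-open), each read covering
    [position, position + read_length).
    """
    if not features:
        raise SchemaError(f"genome {genome_id}: no informative features")
    feat_ids = {f.feature_id for f in features}
    reads = reads[reads["feature_id"].isin(feat_ids)]
    cum_len = sum(f.length for f in features)
    n_reads = len(reads)
    if n_reads == 0:
        return GenomeProfile(genome_id, species, 0, len(features), cum_len,
                             0.0, 0.0, 0.0, 0.0, 0.0)
    covered_features = reads["feature_id"].nunique()
    mask, depth, perfect, aligned = _coverage_arrays(reads, features, read_length)
    covered = mask & (depth > 0)
    n_covered = int(covered.sum())
    n_perfect = int((covered & (perfect > 0)).sum())
    return GenomeProfile(
        genome_id=genome_id,
        species=species,
        n_reads=n_reads,
        n_cds=len(features),
        cumulated_cds_length=cum_len,
        pct_cds_covered=covered_features / len(features) * 100.0,
        pct_sequence_covered=n_covered / cum_len * 100.0,
        mean_coverage=aligned / cum_len,
        pct_mapped_reads=(n_reads / total_good_reads * 100.0)
        if total_good_reads else 0.0,
        pct_perfect_positions=(n_perfect / n_covered * 100.0) if n_covered else 0.0,
    )


def select_candidate_genomes(
    profiles: list[GenomeProfile], cfg: ThresholdConfig | None = None
) -> list[GenomeProfile]:
    """First-pass shortlist: genomes with >= 20% of features read-covered."""
    cfg = cfg or ThresholdConfig()
    return [p for p in profiles if p.pct_cds_covered >= cfg.candidate_min_feature_pct]


def prefilter_genomes(
    profiles: list[GenomeProfile], cfg: ThresholdConfig | None = None
) -> list[GenomeProfile]:
    """Second-pass filter: >= 700 mapped reads and >= 20% CDS covered."""
    cfg = cfg or ThresholdConfig()
    return [
        p for p in profiles
        if p.n_reads >= cfg.genome_min_reads
        and p.pct_cds_covered >= cfg.genome_min_cds_pct
    ]


def call_presence(
    profile: GenomeProfile,
    total_good_reads: int,
    cfg: ThresholdConfig | None = None,
) -> PresenceCall:
    """Two-branch presence rule on reads-per-CDS and CDS breadth.

    avg = n_reads / n_cds.  Present when avg >= 10 with breadth > 80%, or
    2 <= avg < 10 with breadth > 70% ("between 2 and 10" read as the
    half-open interval so the branches partition cleanly at 10).
    """
    cfg = cfg or ThresholdConfig()
    avg = profile.avg_reads_per_cds
    pct = profile.pct_cds_covered
    if avg >= cfg.presence_avg_high and pct > cfg.presence_pct_high:
        present, reason = True, (
            f"avg_reads_per_cds {avg:.2f} >= {cfg.presence_avg_high:g} and "
            f"cds_covered {pct:.1f}% > {cfg.presence_pct_high:g}%"
        )
    elif cfg.presence_avg_low <= avg < cfg.presence_avg_high and pct > cfg.presence_pct_low:
        present, reason = True, (
            f"avg_reads_per_cds {avg:.2f} in [{cfg.presence_avg_low:g}, "
            f"{cfg.presence_avg_high:g}) and cds_covered {pct:.1f}% > "
            f"{cfg.presence_pct_low:g}%"
        )
    else:
        present, reason = False, (
            f"avg_reads_per_cds {avg:.2f} / cds_covered {pct:.1f}% "
            "match neither presence branch"
        )
    return PresenceCall(
        genome_id=profile.genome_id,
        species=profile.species,
        present=present,
        reason=reason,
        relative_abundance=relative_abundance(profile, total_good_reads),
    )


def dedup_species(profiles: list[GenomeProfile]) -> list[GenomeProfile]:
    """Keep one reference per species: highest CDS breadth, ties by id."""
    best: dict[str, GenomeProfile] = {}
    for p in profiles:
        cur = best.get(p.species)
        if (
            cur is None
            or p.pct_cds_covered > cur.pct_cds_covered
            or (p.pct_cds_covered == cur.pct_cds_covered
                and p.genome_id < cur.genome_id)
        ):
            best[p.species] = p
    return [best[s] for s in sorted(best)]


def relative_abundance(profile: GenomeProfile, total_good_reads: int) -> float:
    """Reads assigned to the genome / total good-quality reads."""
    if total_good_reads <= 0:
        raise SchemaError("total_good_reads must be positive")
    return profile.n_reads / total_good_reads


def profile_sample(
    reads: pd.DataFrame,
    annotations: list[GenomeAnnotation],
    cfg: ThresholdConfig | None = None,
    read_length: int = DEFAULT_READ_LENGTH,
) -> tuple[list[GenomeProfile], list[PresenceCall], int]:
    """Full profiling chain on one sample's read table.

    quality filter -> feature masking -> per-genome profiles ->
    candidate selection -> prefilter -> presence calls -> species dedup.
    Returns (deduplicated profiles, their presence calls, n good reads).
    The chain is a deterministic function of its input tables.
    """
    cfg = cfg or ThresholdConfig()
    missing = set(READ_COLUMNS) - set(reads.columns)
    if missing:
        raise SchemaError(f"read table missing columns {sorted(missing)}")
    good, _ = filter_reads_by_quality(reads, cfg.read_q_min)
    total_good = len(good)
    by_genome = dict(tuple(good.groupby("genome_id")))
    profiles = []
    for ann in annotations:
        feats = mask_uninformative_features(ann)
        greads = by_genome.get(ann.genome_id, good.iloc[0:0])
        profiles.append(
            compute_genome_profile(
                greads, feats, total_good, ann.genome_id, ann.species, read_length
            )
        )
    candidates = select_candidate_genomes(profiles, cfg)
    survivors = prefilter_genomes(candidates, cfg)
    called = [p for p in survivors if call_presence(p, total_good, cfg).present]
    final = dedup_species(called)
    calls = [call_presence(p, total_good, cfg) for p in final]
    return final, calls, total_good
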