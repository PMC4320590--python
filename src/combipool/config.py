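"""Every numeric cutoff used by the toolkit, in one place.

The defaults are the published thresholds of the pooled-sequencing
methodology this package implements: the Pearson cutoff for contig
assignment, the six HMP draft-submission criteria, the two chimera
tests, and the metagenomic presence-calling rules.  Keeping them in a
single dataclass means every deviation from the published protocol is
explicit in the run configuration and logged.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .errors import SchemaError


@dataclass
class ThresholdConfig:
    """Numeric cutoffs for deconvolution, QC and profiling.

    Attributes
    ----------
    r_min : float
        Minimum Pearson correlation between a contig's coverage vector and a
        strain's pool signature for assignment (dimensionless, in (0, 1]).
    rho_min : float
        Minimum mean pairwise Spearman rho of per-contig tetranucleotide
        vectors; below this a draft is flagged as contaminated.
    marker_redundancy_min : int
        Number of duplicated single-copy phylogenetic markers at or above
        which a draft is called chimeric.
    min_contig_len : int
        Contigs shorter than this many bases are discarded before analysis.
    tetra_min_contig_len : int
        Contigs shorter than this do not enter the tetranucleotide
        homogeneity test (short contigs give noisy rank correlations).
    min_cluster_eval_size : int
        Clusters below this cumulative size (bases) are skipped by the
        taxonomic purity evaluation.
    min_submit_size : int
        Drafts below this cumulative contig size (bases) are excluded as too
        incomplete.
    read_q_min : float
        Reads with mean base quality strictly below this are bad-quality.
    genome_min_reads : int
        Profiling prefilter: minimum reads mapped to a genome.
    genome_min_cds_pct : float
        Profiling prefilter: minimum percentage of CDS covered by >=1 read.
    candidate_min_feature_pct : float
        First-pass candidate selection: minimum percentage of informative
        features (genes, or 1000-base fragments for unannotated genomes)
        covered by at least one read.
    presence_avg_high, presence_pct_high : float
        First presence branch: reads-per-CDS >= avg_high and CDS coverage
        strictly above pct_high percent.
    presence_avg_low, presence_pct_low : float
        Second branch: avg in [avg_low, avg_high) and CDS coverage strictly
        above pct_low percent.
    hmp_* : HMP draft-genome submission criteria thresholds.
    marker_identity_min, marker_coverage_min : float
        Percent identity / coverage below which a marker hit is ignored.
    """

    r_min: float = 0.95
    rho_min: float = 0.6
    marker_redundancy_min: int = 3
    min_contig_len: int = 100
    tetra_min_contig_len: int = 1000
    min_cluster_eval_size: int = 500_000
    min_submit_size: int = 1_000_000
    read_q_min: float = 20.0
    genome_min_reads: int = 700
    genome_min_cds_pct: float = 20.0
    candidate_min_feature_pct: float = 20.0
    presence_avg_high: float = 10.0
    presence_pct_high: float = 80.0
    presence_avg_low: float = 2.0
    presence_pct_low: float = 70.0
    hmp_n90_min: int = 500
    hmp_essential_min: float = 0.90
    hmp_frac_gt5x_min: float = 0.90
    hmp_depth_fold: float = 5.0
    hmp_contig_n50_min: int = 5_000
    hmp_scaffold_n50_min: int = 20_000
    hmp_mean_contig_min: int = 5_000
    marker_identity_min: float = 50.0
    marker_coverage_min: float = 50.0
    n_essential_genes: int = 99
    n_phylo_markers: int = 40
    tie_epsilon: float = 1e-12

    def validate(self) -> None:
        if not (0.0 < self.r_min <= 1.0):
            raise SchemaError(f"r_min must be in (0, 1], got {self.r_min}")
        for name in (
            "rho_min", "marker_redundancy_min", "min_contig_len",
            "tetra_min_contig_len", "min_cluster_eval_size",
            "min_submit_size", "read_q_min", "genome_min_reads",
            "genome_min_cds_pct", "candidate_min_feature_pct",
            "presence_avg_high", "presence_pct_high", "presence_avg_low",
            "presence_pct_low", "hmp_n90_min", "hmp_essential_min",
            "hmp_frac_gt5x_min", "hmp_depth_fold", "hmp_contig_n50_min",
            "hmp_scaffold_n50_min", "hmp_mean_contig_min",
        ):
            if getattr(self, name) <= 0:
                raise SchemaError(f"threshold {name} must be positive")


@dataclass
class RunConfig:
    """Flat run configuration: thresholds + paths + seed + verbosity.

    Serializes losslessly to a flat key:value YAML mapping (threshold
    fields at top level, prefixed by nothing; paths stored as strings).
    """

    thresholds: ThresholdConfig = field(default_factory=ThresholdConfig)
    seed: int = 0
    out_dir: str = "combipool_out"
    log_level: str = "INFO"
    normalize_depths: bool = True
    paths: dict[str, str] = field(default_factory=dict)

    _PATH_KEYS = (
        "manifest", "contigs", "depths", "signatures", "assignments",
        "markers40", "essential99", "tax", "reads", "annotations",
    )

    def to_dict(self) -> dict[str, Any]:
        d: dict[str, Any] = dataclasses.asdict(self.thresholds)
        d["seed"] = self.seed
        d["out_dir"] = self.out_dir
        d["log_level"] = self.log_level
        d["normalize_depths"] = self.normalize_depths
        for k, v in sorted(self.paths.items()):
            d[f"path_{k}"] = v
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        d = dict(d)
        paths = {k[5:]: str(d.pop(k)) for k in list(d) if k.startswith("path_")}
        seed = int(d.pop("seed", 0))
        out_dir = str(d.pop("out_dir", "combipool_out"))
        log_level = str(d.pop("log_level", "INFO"))
        normalize_depths = bool(d.pop("normalize_depths", True))
        known = {f.name for f in dataclasses.fields(ThresholdConfig)}
        unknown = set(d) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        thr = ThresholdConfig(**d)
        thr.validate()
        return cls(thresholds=thr, seed=seed, out_dir=out_dir,
                   log_level=log_level, normalize_depths=normalize_depths,
                   paths=paths)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise SchemaError(f"config file {path} is not a flat mapping")
        return cls.from_dict(data)
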