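"""Synthetic data with known ground truth for every pipeline stage.

Real pooled-sequencing inputs (compositionally distinct genomes,
assembly fragmentation, pool-signature-proportional depths with
multiplicative noise, chimeric contamination, multinomially allocated
metagenomic reads) are emulated here so the deconvolution, QC and
profiling stages can be exercised offline against a recorded truth.

Genome composition comes from either a GC-bias model (i.i.d. bases with
a target GC content) or an order-k Markov chain over {A,C,G,T}; distinct
strains get distinct transition tables so their tetranucleotide
signatures are separable — the property the chimera test relies on.
Depth noise is multiplicative lognormal, since real coverage is positive
and heavy-tailed.  All generators are reproducible under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .covmatrix import Contig, DepthMatrix
from .errors import SchemaError
from .pooldesign import SignatureMatrix, design_signature_matrix
from .profiler import (
    DEFAULT_READ_LENGTH,
    Feature,
    GenomeAnnotation,
    mask_uninformative_features,
)
from .qc import MARKER_COLUMNS

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class CompositionModel:
    """Sequence composition: GC-bias (iid) or order-k Markov chain."""

    mode: str  # "gc" | "markov"
    gc: float = 0.5
    order: int = 3
    transitions: np.ndarray | None = None  # shape (4**order, 4), rows sum to 1

    @classmethod
    def gc_bias(cls, gc: float) -> "CompositionModel":
        if not 0.0 < gc < 1.0:
            raise SchemaError(f"GC fraction must be in (0,1), got {gc}")
        return cls(mode="gc", gc=gc)

    @classmethod
    def random_markov(
        cls, seed: int, order: int = 3, concentration: float = 1.0
    ) -> "CompositionModel":
        """Dirichlet-sampled transition table; low concentration -> strong
        compositional idiosyncrasy (distinct strains separate well)."""
        rng = np.random.default_rng(seed)
        t = rng.dirichlet([concentration] * 4, size=4 ** order)
        return cls(mode="markov", order=order, transitions=t)

    def validate(self) -> None:
        if self.mode == "gc":
            if not 0.0 < self.gc < 1.0:
                raise SchemaError("invalid GC fraction")
        elif self.mode == "markov":
            if self.transitions is None or self.transitions.shape != (
                4 ** self.order, 4
            ):
                raise SchemaError("markov model needs a (4^order, 4) table")
            if not np.allclose(self.transitions.sum(axis=1), 1.0):
                raise SchemaError("transition rows must sum to 1")
        else:
            raise SchemaError(f"unknown composition mode {self.mode!r}")


@dataclass
class GroundTruth:
    """What the generators actually planted, for downstream scoring."""

    contig_to_strain: dict[str, str] = field(default_factory=dict)
    genome_abundance: dict[str, float] = field(default_factory=dict)
    contaminant_contigs: dict[str, set[str]] = field(default_factory=dict)


def generate_genome(length: int, model: CompositionModel, seed: int) -> str:
    """Random nucleotide sequence from the composition model."""
    if length < 1:
        raise SchemaError("genome length must be >= 1")
    model.validate()
    rng = np.random.default_rng(seed)
    if model.mode == "gc":
        p = np.array([(1 - model.gc) / 2, model.gc / 2, model.gc / 2,
                      (1 - model.gc) / 2])
        codes = rng.choice(4, size=length, p=p)
        return _BASES[codes].tobytes().decode("ascii")
    k = model.order
    cum = np.cumsum(model.transitions, axis=1)
    out = np.empty(length, dtype=np.int64)
    # seed context uniformly
    for i in range(min(k, length)):
        out[i] = rng.integers(4)
    if length <= k:
        return _BASES[out].tobytes().decode("ascii")
    u = rng.random(length - k)
    ctx = 0
    for i in range(k):
        ctx = ctx * 4 + out[i]
    mask = 4 ** (k - 1)
    for i in range(k, length):
        b = int(np.searchsorted(cum[ctx], u[i - k], side="right"))
        b = min(b, 3)
        out[i] = b
        ctx = (ctx % mask) * 4 + b
    return _BASES[out].tobytes().decode("ascii")


def shred_genome(
    genome: str,
    mean_contig_len: int,
    min_len: int = 100,
    seed: int = 0,
    contig_prefix: str = "contig",
    assembly_pool_id: int = 0,
) -> list[Contig]:
    """Tile a genome into contigs of roughly ``mean_contig_len`` bases.

    Breakpoints are evenly spaced with uniform jitter, then adjusted so
    every piece is at least ``min_len``; pieces concatenate back to the
    genome exactly (assembly fragmentation loses order, not sequence —
    order is irrelevant downstream).
    """
    if mean_contig_len < min_len:
        raise SchemaError("mean_contig_len must be >= min_len")
    L = len(genome)
    n = max(1, round(L / mean_contig_len))
    while n > 1 and L / n < min_len:
        n -= 1
    rng = np.random.default_rng(seed)
    seg = L / n
    cuts = [0]
    for i in range(1, n):
        jitter = rng.uniform(-0.25, 0.25) * seg
        pos = int(round(i * seg + jitter))
        pos = max(pos, cuts[-1] + min_len)
        pos = min(pos, L - (n - i) * min_len)
        cuts.append(pos)
    cuts.append(L)
    contigs = []
    for i in range(n):
        s, e = cuts[i], cuts[i + 1]
        contigs.append(
            Contig(
                contig_id=f"{contig_prefix}_{i + 1:04d}",
                assembly_pool_id=assembly_pool_id,
                length=e - s,
                sequence=genome[s:e],
            )
        )
    return contigs


def simulate_depth_matrix(
    clusters: dict[str, list[Contig]],
    signatures: SignatureMatrix,
    base_depth: float = 30.0,
    noise_sigma: float = 0.0,
    dropout_p: float = 0.0,
    seed: int = 0,
) -> tuple[DepthMatrix, GroundTruth]:
    """Pool-signature-proportional depths with multiplicative noise.

    depth(contig, pool) = base_depth * signature(strain, pool) *
    LogNormal(0, noise_sigma), zeroed with probability ``dropout_p``.
    """
    for sid in clusters:
        if sid not in signatures.strain_ids:
            raise SchemaError(f"strain {sid} has no signature row")
    rng = np.random.default_rng(seed)
    contig_ids: list[str] = []
    lengths: dict[str, int] = {}
    truth = GroundTruth()
    rows = []
    for sid in signatures.strain_ids:
        sig = signatures.row(sid).astype(float)
        for c in clusters.get(sid, []):
            depth = base_depth * sig
            if noise_sigma > 0:
                depth = depth * rng.lognormal(0.0, noise_sigma, size=sig.size)
            if dropout_p > 0:
                depth = np.where(rng.random(sig.size) < dropout_p, 0.0, depth)
            contig_ids.append(c.contig_id)
            lengths[c.contig_id] = c.length
            truth.contig_to_strain[c.contig_id] = sid
            rows.append(depth)
    matrix = np.array(rows) if rows else np.zeros((0, signatures.n_pools))
    lens = np.array([lengths[c] for c in contig_ids], dtype=float)
    pool_totals = (matrix * lens[:, None]).sum(axis=0) if rows else np.zeros(
        signatures.n_pools
    )
    return (
        DepthMatrix(contig_ids, matrix, pool_totals, lengths),
        truth,
    )


def inject_contamination(
    cluster_contigs: list[Contig],
    donor_contigs: list[Contig],
    fraction: float,
    seed: int = 0,
) -> tuple[list[Contig], GroundTruth]:
    """Replace ceil(fraction * n) contigs of a draft with donor contigs.

    Emulates clustering mis-assignment; contig count is conserved and the
    truth records which members are foreign.
    """
    if not 0.0 <= fraction <= 1.0:
        raise SchemaError("fraction must be in [0, 1]")
    n = len(cluster_contigs)
    k = math.ceil(fraction * n)
    if k > len(donor_contigs):
        raise SchemaError(f"need {k} donor contigs, have {len(donor_contigs)}")
    rng = np.random.default_rng(seed)
    replaced_idx = set(rng.choice(n, size=k, replace=False).tolist()) if k else set()
    donors = list(rng.choice(len(donor_contigs), size=k, replace=False)) if k else []
    out: list[Contig] = []
    truth = GroundTruth()
    contaminants: set[str] = set()
    di = 0
    for i, c in enumerate(cluster_contigs):
        if i in replaced_idx:
            d = donor_contigs[donors[di]]
            di += 1
            out.append(d)
            contaminants.add(d.contig_id)
        else:
            out.append(c)
    truth.contaminant_contigs["draft"] = contaminants
    return out, truth


def simulate_marker_hits(
    draft_ids: list[str],
    duplication_spec: dict[str, list[str]] | None = None,
    n_markers: int = 40,
    marker_prefix: str = "m",
    present_fraction: float = 1.0,
    seed: int = 0,
) -> dict[str, pd.DataFrame]:
    """Marker-hit tables per draft (identity/coverage drawn in 60..100).

    A clean draft hits each marker of the catalog once; markers listed in
    ``duplication_spec[draft]`` appear twice (the chimera signal).  With
    ``present_fraction`` < 1 a random subset of markers is missing, which
    drives completeness below 100%.
    """
    duplication_spec = duplication_spec or {}
    rng = np.random.default_rng(seed)
    markers = [f"{marker_prefix}{i + 1:02d}" for i in range(n_markers)]
    tables = {}
    for draft in draft_ids:
        n_present = round(present_fraction * n_markers)
        present = sorted(
            rng.choice(n_markers, size=n_present, replace=False).tolist()
        )
        rows = []
        for idx in present:
            m = markers[idx]
            copies = 2 if m in duplication_spec.get(draft, []) else 1
            for c in range(copies):
                rows.append(
                    (
                        m,
                        f"{draft}_c{idx + 1:03d}_{c}",
                        float(rng.uniform(60, 100)),
                        float(rng.uniform(60, 100)),
                    )
                )
        tables[draft] = pd.DataFrame(rows, columns=MARKER_COLUMNS)
    return tables


def simulate_annotations(
    n_genomes: int,
    n_cds: int = 50,
    cds_len: int = 900,
    gap: int = 100,
    seed: int = 0,
) -> list[GenomeAnnotation]:
    """Simple annotated reference genomes: ``n_cds`` CDS separated by gaps."""
    anns = []
    for g in range(n_genomes):
        feats = []
        pos = 0
        for i in range(n_cds):
            feats.append(Feature(f"g{g + 1}_cds{i + 1:04d}", pos, pos + cds_len))
            pos += cds_len + gap
        anns.append(
            GenomeAnnotation(
                genome_id=f"genome_{g + 1}",
                species=f"species_{g + 1}",
                features=feats,
                genome_length=pos,
            )
        )
    return anns


def simulate_read_profiles(
    annotations: list[GenomeAnnotation],
    abundances: list[float],
    n_reads: int,
    perfect_fraction: float = 1.0,
    bad_quality_fraction: float = 0.0,
    read_length: int = DEFAULT_READ_LENGTH,
    seed: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Multinomial read allocation across genomes and their CDS.

    Reads go to genomes with probability proportional to abundance, then
    to informative features proportionally to feature length, at a
    uniform position inside the feature.  Mismatches are 0 with
    probability ``perfect_fraction``, else 1-3.  Mean qualities are drawn
    so that ``bad_quality_fraction`` of reads falls below 20.
    """
    if len(annotations) != len(abundances):
        raise SchemaError("one abundance per genome required")
    ab = np.asarray(abundances, dtype=float)
    if not np.isclose(ab.sum(), 1.0):
        raise SchemaError("abundances must sum to 1")
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_reads, ab)
    rows = []
    truth = GroundTruth(genome_abundance={
        a.genome_id: float(x) for a, x in zip(annotations, ab)
    })
    rid = 0
    for ann, c in zip(annotations, counts):
        feats = mask_uninformative_features(ann)
        w = np.array([f.length for f in feats], dtype=float)
        fidx = rng.choice(len(feats), size=c, p=w / w.sum())
        for j in fidx:
            f = feats[j]
            hi = max(f.start, f.end - read_length)
            pos = int(rng.integers(f.start, hi + 1))
            mm = 0 if rng.random() < perfect_fraction else int(rng.integers(1, 4))
            if rng.random() < bad_quality_fraction:
                q = float(rng.uniform(5.0, 19.5))
            else:
                q = float(rng.uniform(25.0, 40.0))
            rows.append(
                (f"r{rid:07d}", q, ann.genome_id, f.feature_id, mm, pos)
            )
            rid += 1
    reads = pd.DataFrame(
        rows,
        columns=["read_id", "mean_quality", "genome_id", "feature_id",
                 "mismatches", "position"],
    )
    return reads, truth


def simulate_pool_experiment(
    n_strains: int = 12,
    genome_length: int = 200_000,
    mean_contig_len: int = 5_000,
    n_comb_pools: int = 6,
    base_depth: float = 30.0,
    noise_sigma: float = 0.0,
    dropout_p: float = 0.0,
    with_sequences: bool = False,
    seed: int = 0,
) -> tuple[dict[str, list[Contig]], SignatureMatrix, DepthMatrix, GroundTruth]:
    """One assembly pool end to end: strains, signatures, contigs, depths.

    The default scale (12 strains x 200 kb, ~40 contigs each, 6
    combinatorial pools) runs in seconds on one CPU while exercising the
    same geometry as a real pooled experiment.  ``with_sequences`` draws a
    distinct Markov composition per strain; deconvolution itself only
    needs contig lengths, so sequences are off by default.
    """
    rng = np.random.default_rng(seed)
    strain_ids = [f"strain_{i + 1:02d}" for i in range(n_strains)]
    signatures = design_signature_matrix(strain_ids, n_comb_pools,
                                         seed=int(rng.integers(2 ** 31)))
    clusters: dict[str, list[Contig]] = {}
    for i, sid in enumerate(strain_ids):
        gseed = int(rng.integers(2 ** 31))
        if with_sequences:
            model = CompositionModel.random_markov(gseed, order=3)
            genome = generate_genome(genome_length, model, gseed + 1)
            contigs = shred_genome(
                genome, mean_contig_len, seed=gseed + 2, contig_prefix=sid
            )
        else:
            n = max(1, round(genome_length / mean_contig_len))
            lens = rng.integers(
                max(100, mean_contig_len // 2), mean_contig_len * 3 // 2, size=n
            )
            contigs = [
                Contig(f"{sid}_{j + 1:04d}", 0, int(L)) for j, L in enumerate(lens)
            ]
        clusters[sid] = contigs
    matrix, truth = simulate_depth_matrix(
        clusters, signatures, base_depth, noise_sigma, dropout_p,
        seed=int(rng.integers(2 ** 31)),
    )
    return clusters, signatures, matrix, truth
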