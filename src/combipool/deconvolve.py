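"""Co-abundance deconvolution: contigs -> strains by Pearson correlation.

A contig assembled from a pooled library inherits its source strain's
presence pattern across the combinatorial pools: wherever the strain's
DNA was pooled, the contig has depth; elsewhere it has (near) none.
Correlating each contig's coverage vector against every candidate
strain's binary signature and keeping the best match — provided the
correlation reaches the cutoff (default 0.95) — attributes contigs to
strains without per-strain libraries.

Assignment decisions are invariant under positive rescaling of the
coverage vector (Pearson is affine-invariant), so uneven pool yields
only matter through column-wise, not row-wise, distortion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .config import ThresholdConfig
from .covmatrix import DepthMatrix
from .errors import SchemaError, UndefinedCorrelationError
from .pooldesign import SignatureMatrix

UNASSIGNED = "UNASSIGNED"


@dataclass(frozen=True)
class Assignment:
    contig_id: str
    assigned_strain: str  # strain_id or UNASSIGNED
    best_r: float | None  # None when correlation undefined for all strains


@dataclass
class DraftCluster:
    """All contigs attributed to one strain."""

    strain_id: str
    contig_ids: list[str] = field(default_factory=list)
    total_length: int = 0


@dataclass
class UnassignedSummary:
    contig_ids: list[str] = field(default_factory=list)
    count: int = 0
    total_length: int = 0


def pearson_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Product-moment correlation of two equal-length vectors.

    Raises UndefinedCorrelationError when either vector has zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise SchemaError("pearson_correlation needs two equal-length vectors (n >= 2)")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero variance vector")
    return float(stats.pearsonr(x, y).statistic)


def assign_contig(
    cov: np.ndarray,
    signatures: SignatureMatrix,
    r_min: float = 0.95,
    tie_epsilon: float = 1e-12,
    contig_id: str = "",
) -> Assignment:
    """Assign one coverage vector to the best-correlated strain signature.

    The contig goes to the strain with the highest Pearson correlation if
    that maximum is at least ``r_min`` and is unique (two strains within
    ``tie_epsilon`` of the maximum make the contig unidentifiable).
    Degenerate vectors — constant coverage, hence undefined correlation —
    are UNASSIGNED rather than an error, since real pools produce them.
    """
    cov = np.asarray(cov, dtype=float)
    if cov.size != signatures.n_pools:
        raise SchemaError(
            f"coverage vector length {cov.size} != {signatures.n_pools} pools"
        )
    if np.ptp(cov) == 0:
        return Assignment(contig_id, UNASSIGNED, None)
    best_r = -np.inf
    best_strain: str | None = None
    tied = False
    for sid, sig in zip(signatures.strain_ids, signatures.matrix):
        try:
            r = pearson_correlation(cov, sig)
        except UndefinedCorrelationError:
            continue
        if r > best_r + tie_epsilon:
            best_r, best_strain, tied = r, sid, False
        elif abs(r - best_r) <= tie_epsilon:
            tied = True
    if best_strain is None:
        return Assignment(contig_id, UNASSIGNED, None)
    if tied or best_r < r_min:
        return Assignment(contig_id, UNASSIGNED, float(best_r))
    return Assignment(contig_id, best_strain, float(best_r))


def deconvolve_pool(
    m: DepthMatrix,
    signatures: SignatureMatrix,
    cfg: ThresholdConfig | None = None,
) -> tuple[list[DraftCluster], UnassignedSummary, list[Assignment]]:
    """Cluster every contig of one assembly pool to its source strain.

    ``signatures`` must be restricted to this assembly pool's strains;
    deconvolution never runs across assembly pools, each pool's coverage
    matrix being independent.

    Returns the per-strain clusters (every signature strain gets a
    cluster, possibly empty), a summary of unassigned contigs, and the
    full per-contig assignment list.
    """
    cfg = cfg or ThresholdConfig()
    if m.n_pools != signatures.n_pools:
        raise SchemaError(
            f"depth matrix has {m.n_pools} pools, signatures {signatures.n_pools}"
        )
    clusters = {sid: DraftCluster(sid) for sid in signatures.strain_ids}
    unassigned = UnassignedSummary()
    assignments: list[Assignment] = []
    for cid, cov in zip(m.contig_ids, m.matrix):
        a = assign_contig(cov, signatures, cfg.r_min, cfg.tie_epsilon, cid)
        assignments.append(a)
        length = m.contig_lengths[cid]
        if a.assigned_strain == UNASSIGNED:
            unassigned.contig_ids.append(cid)
            unassigned.count += 1
            unassigned.total_length += length
        else:
            cl = clusters[a.assigned_strain]
            cl.contig_ids.append(cid)
            cl.total_length += length
    return list(clusters.values()), unassigned, assignments
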