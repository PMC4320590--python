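"""Per-contig coverage matrix over combinatorial pools.

The deconvolution input: for each contig of an assembly pool, its mean
fold coverage (mapped bases / contig length) in each combinatorial
pool.  Depth is expressed as fold coverage rather than read count so
the matrix is robust to read-length differences between platforms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import SchemaError

DEPTH_COLUMNS = ["contig_id", "pool_id", "mapped_bases"]


@dataclass(frozen=True)
class Contig:
    contig_id: str
    assembly_pool_id: int = 0
    length: int = 0
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.length < 1:
            raise SchemaError(f"contig {self.contig_id}: length must be >= 1")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise SchemaError(
                f"contig {self.contig_id}: sequence length "
                f"{len(self.sequence)} != declared length {self.length}"
            )


@dataclass
class DepthMatrix:
    """Mean fold coverage per (contig, combinatorial pool).

    ``matrix[i, p]`` is the depth of ``contig_ids[i]`` in pool p+1.
    ``pool_totals`` holds total mapped bases per pool (pre-normalization).
    """

    contig_ids: list[str]
    matrix: np.ndarray  # shape (n_contigs, n_pools), float, >= 0
    pool_totals: np.ndarray  # shape (n_pools,), mapped bases
    contig_lengths: dict[str, int]

    @property
    def n_pools(self) -> int:
        return self.matrix.shape[1]

    def row(self, contig_id: str) -> np.ndarray:
        return self.matrix[self.contig_ids.index(contig_id)]


def filter_contigs(
    contigs: Iterable[Contig], min_len: int = 100
) -> list[Contig]:
    """Keep contigs of at least ``min_len`` bases, preserving order."""
    return [c for c in contigs if c.length >= min_len]


def build_depth_matrix(
    depth_records: pd.DataFrame,
    contigs: list[Contig],
    n_pools: int,
    normalize: bool = True,
) -> DepthMatrix:
    """Aggregate per-pool mapped bases into a mean-fold-coverage matrix.

    Parameters
    ----------
    depth_records : DataFrame with columns contig_id, pool_id, mapped_bases.
        Multiple records for the same (contig, pool) are summed.
    contigs : the contig set (defines row order and lengths).
    n_pools : number of combinatorial pools (columns); pool ids are 1-based.
    normalize : divide each pool's column by its total mapped bases and
        rescale by the mean pool total, correcting uneven sequencing yield
        between pools while keeping depths on a fold-coverage scale.

    Missing (contig, pool) pairs give 0.  Unknown contig or pool ids raise.
    """
    missing = set(DEPTH_COLUMNS) - set(depth_records.columns)
    if missing:
        raise SchemaError(f"depth table missing columns {sorted(missing)}")
    index = {c.contig_id: i for i, c in enumerate(contigs)}
    lengths = {c.contig_id: c.length for c in contigs}
    mat = np.zeros((len(contigs), n_pools), dtype=float)
    totals = np.zeros(n_pools, dtype=float)
    cid = depth_records["contig_id"].to_numpy()
    pid = depth_records["pool_id"].to_numpy()
    mb = depth_records["mapped_bases"].to_numpy(dtype=float)
    for c, p, b in zip(cid, pid, mb):
        if c not in index:
            raise SchemaError(f"depth record references unknown contig {c!r}")
        p = int(p)
        if not (1 <= p <= n_pools):
            raise SchemaError(f"pool id {p} outside [1, {n_pools}]")
        if b < 0:
            raise SchemaError(f"negative mapped_bases for contig {c!r}")
        mat[index[c], p - 1] += b / lengths[c]
        totals[p - 1] += b
    if normalize:
        scale = np.where(totals > 0, totals, 1.0)
        mat = mat / scale * totals.mean()
    return DepthMatrix(
        contig_ids=[c.contig_id for c in contigs],
        matrix=mat,
        pool_totals=totals,
        contig_lengths=lengths,
    )


def depths_from_sam(sam_paths: dict[int, str]) -> pd.DataFrame:
    """Aggregate SAM alignments into the depth-table schema.

    ``sam_paths`` maps 1-based pool id -> SAM file of that pool's reads
    aligned to the contigs.  Each mapped record contributes its aligned
    query length to (reference contig, pool).  Alignment itself is out of
    scope; this is a convenience ingestion path.
    """
    import pysam

    rows: list[tuple[str, int, int]] = []
    for pool_id, path in sorted(sam_paths.items()):
        acc: dict[str, int] = {}
        with pysam.AlignmentFile(path, "r", check_sq=False) as sam:
            for rec in sam:
                if rec.is_unmapped or rec.reference_name is None:
                    continue
                aligned = rec.query_alignment_length or 0
                acc[rec.reference_name] = acc.get(rec.reference_name, 0) + aligned
        rows.extend((cid, pool_id, bases) for cid, bases in sorted(acc.items()))
    return pd.DataFrame(rows, columns=DEPTH_COLUMNS)
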