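"""Readers and writers for the toolkit's file formats.

FASTA goes through Biopython; tables are TSV with a header line and a
fixed column order, validated on read so schema drift fails loudly.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .covmatrix import Contig, DepthMatrix, DEPTH_COLUMNS
from .deconvolve import Assignment
from .errors import SchemaError
from .pooldesign import SignatureMatrix, StrainRecord
from .qc import MARKER_COLUMNS, TAX_COLUMNS, QualityReport
from .profiler import READ_COLUMNS, Feature, GenomeAnnotation

MANIFEST_COLUMNS = ["strain_id", "genus", "species", "assembly_pool"]
ANNOTATION_COLUMNS = ["genome_id", "species", "feature_id", "start", "end",
                      "kind", "product"]
ASSIGNMENT_COLUMNS = ["contig_id", "strain_id", "best_r"]


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """(id, sequence) pairs; sequences uppercased for analysis."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append((rec.id, str(rec.seq).upper()))
    return records


def write_fasta(records: list[tuple[str, str]], path: str | Path) -> None:
    seqs = [SeqRecord(Seq(s), id=i, description="") for i, s in records]
    SeqIO.write(seqs, str(path), "fasta")


def contigs_from_fasta(path: str | Path, assembly_pool_id: int = 0) -> list[Contig]:
    return [
        Contig(cid, assembly_pool_id, len(seq), seq)
        for cid, seq in read_fasta(path)
    ]


def _read_tsv(path: str | Path, columns: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(columns) - set(df.columns)
    if missing:
        raise SchemaError(
            f"{path}: missing columns {sorted(missing)}; found {list(df.columns)}"
        )
    return df[columns]


def _write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_manifest(path: str | Path) -> list[StrainRecord]:
    df = _read_tsv(path, MANIFEST_COLUMNS)
    return [
        StrainRecord(str(r.strain_id), str(r.genus), str(r.species),
                     int(r.assembly_pool))
        for r in df.itertuples()
    ]


def write_manifest(strains: list[StrainRecord], path: str | Path) -> None:
    _write_tsv(
        pd.DataFrame(
            [(s.strain_id, s.genus, s.species, s.assembly_pool_id)
             for s in strains],
            columns=MANIFEST_COLUMNS,
        ),
        path,
    )


def read_depth_table(path: str | Path) -> pd.DataFrame:
    return _read_tsv(path, DEPTH_COLUMNS)


def write_depth_table(df: pd.DataFrame, path: str | Path) -> None:
    _write_tsv(df[DEPTH_COLUMNS], path)


def write_signature_matrix(m: SignatureMatrix, path: str | Path) -> None:
    cols = [f"pool_{p + 1}" for p in range(m.n_pools)]
    df = pd.DataFrame(m.matrix, columns=cols)
    df.insert(0, "strain_id", m.strain_ids)
    _write_tsv(df, path)


def read_signature_matrix(path: str | Path) -> SignatureMatrix:
    df = pd.read_csv(path, sep="\t")
    if "strain_id" not in df.columns or df.shape[1] < 2:
        raise SchemaError(f"{path}: not a signature matrix TSV")
    pools = [c for c in df.columns if c != "strain_id"]
    return SignatureMatrix(
        [str(s) for s in df["strain_id"]], df[pools].to_numpy()
    )


def write_assignments(assignments: list[Assignment], path: str | Path) -> None:
    _write_tsv(
        pd.DataFrame(
            [(a.contig_id, a.assigned_strain,
              "" if a.best_r is None else f"{a.best_r:.6f}")
             for a in assignments],
            columns=ASSIGNMENT_COLUMNS,
        ),
        path,
    )


def read_marker_table(path: str | Path) -> pd.DataFrame:
    return _read_tsv(path, MARKER_COLUMNS)


def read_tax_table(path: str | Path) -> pd.DataFrame:
    return _read_tsv(path, TAX_COLUMNS)


def read_read_table(path: str | Path) -> pd.DataFrame:
    return _read_tsv(path, READ_COLUMNS)


def write_read_table(df: pd.DataFrame, path: str | Path) -> None:
    _write_tsv(df[READ_COLUMNS], path)


def read_annotations(path: str | Path) -> list[GenomeAnnotation]:
    """Annotation TSV -> per-genome feature sets (0-based half-open)."""
    df = _read_tsv(path, ANNOTATION_COLUMNS)
    anns = []
    for (gid, species), group in df.groupby(["genome_id", "species"], sort=True):
        feats = [
            Feature(str(r.feature_id), int(r.start), int(r.end), str(r.kind),
                    "" if pd.isna(r.product) else str(r.product))
            for r in group.itertuples()
        ]
        anns.append(
            GenomeAnnotation(str(gid), str(species), feats,
                             genome_length=max(f.end for f in feats))
        )
    return anns


def write_annotations(anns: list[GenomeAnnotation], path: str | Path) -> None:
    rows = [
        (a.genome_id, a.species, f.feature_id, f.start, f.end, f.kind, f.product)
        for a in anns
        for f in a.features
    ]
    _write_tsv(pd.DataFrame(rows, columns=ANNOTATION_COLUMNS), path)


def quality_reports_to_frame(reports: list[QualityReport]) -> pd.DataFrame:
    """One row per draft with all QC metrics and the tier."""
    rows = []
    for r in reports:
        rows.append(
            {
                "strain_id": r.strain_id,
                "n_contigs": r.metrics.n_contigs,
                "total_length": r.metrics.total_length,
                "contig_N50": r.metrics.contig_N50,
                "contig_N90": r.metrics.contig_N90,
                "mean_contig_length": round(r.metrics.mean_contig_length, 1),
                "scaffold_N50": r.metrics.scaffold_N50,
                "frac_bases_gt5x": (
                    "" if r.metrics.frac_bases_gt5x is None
                    else round(r.metrics.frac_bases_gt5x, 4)
                ),
                "essential_fraction": round(r.essential_fraction, 4),
                "tetra_mean_rho": (
                    "" if r.tetra_mean_rho is None else round(r.tetra_mean_rho, 4)
                ),
                "tetra_contaminated": r.tetra_contaminated,
                "n_redundant_markers": r.n_redundant_markers,
                "marker_chimeric": r.marker_chimeric,
                "hmp_all_pass": r.hmp.all_pass,
                "tier": r.tier,
            }
        )
    return pd.DataFrame(rows)
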