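"""Config-driven orchestration of the analysis chains.

Two chains exist: the genome-reconstruction chain
(coverage matrix -> deconvolution -> per-cluster QC) and the
metagenomic profiling chain (read table -> profiles -> presence calls).
Every threshold in use is logged, and reruns of the same configuration
produce byte-identical reports.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

from . import io
from .config import RunConfig
from .covmatrix import build_depth_matrix, filter_contigs
from .deconvolve import deconvolve_pool
from .errors import CombipoolError, SchemaError
from .profiler import profile_sample
from .qc import cluster_purity, evaluate_draft

log = logging.getLogger("combipool")


def _log_thresholds(config: RunConfig) -> None:
    for f in dataclasses.fields(config.thresholds):
        log.info("threshold %s = %s", f.name, getattr(config.thresholds, f.name))


def run_deconvolution_chain(config: RunConfig) -> dict[str, str]:
    """coverage -> deconvolve (-> QC when marker tables are provided)."""
    cfg = config.thresholds
    cfg.validate()
    _log_thresholds(config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = config.paths
    for key in ("contigs", "depths", "signatures"):
        if key not in paths:
            raise SchemaError(f"deconvolution chain needs path_{key} in config")
    contigs = io.contigs_from_fasta(paths["contigs"])
    contigs = filter_contigs(contigs, cfg.min_contig_len)
    depths = io.read_depth_table(paths["depths"])
    signatures = io.read_signature_matrix(paths["signatures"])
    matrix = build_depth_matrix(
        depths, contigs, signatures.n_pools, normalize=config.normalize_depths
    )
    clusters, unassigned, assignments = deconvolve_pool(matrix, signatures, cfg)
    report_paths: dict[str, str] = {}
    ap = out / "assignments.tsv"
    io.write_assignments(assignments, ap)
    report_paths["assignments"] = str(ap)
    by_id = {c.contig_id: c for c in contigs}
    for cl in clusters:
        if cl.contig_ids:
            fp = out / f"cluster_{cl.strain_id}.fasta"
            io.write_fasta(
                [(cid, by_id[cid].sequence or "") for cid in cl.contig_ids], fp
            )
            report_paths[f"cluster_{cl.strain_id}"] = str(fp)
    summary = {
        "n_contigs": len(contigs),
        "n_assigned": sum(len(c.contig_ids) for c in clusters),
        "n_unassigned": unassigned.count,
        "unassigned_length": unassigned.total_length,
    }
    if "markers40" in paths and "essential99" in paths:
        m40 = io.read_marker_table(paths["markers40"])
        e99 = io.read_marker_table(paths["essential99"])
        reports = []
        for cl in clusters:
            if not cl.contig_ids:
                continue
            members = [by_id[c] for c in cl.contig_ids]
            cids = set(cl.contig_ids)
            reports.append(
                evaluate_draft(
                    cl.strain_id,
                    members,
                    e99[e99["contig_id"].isin(cids)],
                    m40[m40["contig_id"].isin(cids)],
                    cfg=cfg,
                )
            )
        qp = out / "qc_report.tsv"
        io.quality_reports_to_frame(reports).to_csv(qp, sep="\t", index=False)
        report_paths["qc_report"] = str(qp)
        if "tax" in paths:
            tax = io.read_tax_table(paths["tax"])
            lengths = {c.contig_id: c.length for c in contigs}
            purity = {}
            for cl in clusters:
                if not cl.contig_ids:
                    continue
                res = cluster_purity(cl, tax, lengths, cfg)
                purity[cl.strain_id] = (
                    "SKIPPED" if res is None
                    else {"dominant_genus_pct": round(res[0], 2),
                          "reference_coverage_pct": round(res[1], 2)}
                )
            summary["purity"] = purity
    sp = out / "summary.json"
    sp.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    report_paths["summary"] = str(sp)
    return report_paths


def run_profiling_chain(config: RunConfig) -> dict[str, str]:
    """read table -> genome profiles -> presence calls -> abundances."""
    cfg = config.thresholds
    cfg.validate()
    _log_thresholds(config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = config.paths
    for key in ("reads", "annotations"):
        if key not in paths:
            raise SchemaError(f"profiling chain needs path_{key} in config")
    reads = io.read_read_table(paths["reads"])
    annotations = io.read_annotations(paths["annotations"])
    profiles, calls, total_good = profile_sample(reads, annotations, cfg)
    import pandas as pd

    rows = []
    for p, c in zip(profiles, calls):
        rows.append(
            {
                "genome_id": p.genome_id,
                "species": p.species,
                "n_reads": p.n_reads,
                "n_cds": p.n_cds,
                "cumulated_cds_length": p.cumulated_cds_length,
                "pct_cds_covered": round(p.pct_cds_covered, 2),
                "pct_sequence_covered": round(p.pct_sequence_covered, 2),
                "mean_coverage": round(p.mean_coverage, 3),
                "pct_mapped_reads": round(p.pct_mapped_reads, 3),
                "pct_perfect_positions": round(p.pct_perfect_positions, 2),
                "present": c.present,
                "relative_abundance": round(c.relative_abundance, 6),
            }
        )
    pp = out / "profile.tsv"
    pd.DataFrame(rows).to_csv(pp, sep="\t", index=False)
    sp = out / "profile_summary.json"
    sp.write_text(
        json.dumps(
            {"total_good_reads": total_good,
             "n_present": sum(c.present for c in calls)},
            indent=2, sort_keys=True,
        )
        + "\n"
    )
    return {"profile": str(pp), "summary": str(sp)}


def run_pipeline(config: RunConfig) -> dict[str, str]:
    """Dispatch on the configured inputs; raises CombipoolError on failure."""
    logging.basicConfig(level=config.log_level)
    if "reads" in config.paths:
        return run_profiling_chain(config)
    if "contigs" in config.paths:
        return run_deconvolution_chain(config)
    raise CombipoolError(
        "config provides neither path_reads (profiling) nor path_contigs "
        "(deconvolution)"
    )
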