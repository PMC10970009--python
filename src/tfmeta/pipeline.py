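"""End-to-end orchestration: qc -> contributions -> scan -> {enrich,
footprint} x {prom, enhD} -> aggregate -> correlate -> summarize.

Every stage consumes and produces plain files (TSV/MTX/BED), so any stage
can be re-run independently and shell/R users can consume intermediates.
A manifest with input/output hashes, seeds and library versions is written
at the end; reruns with identical config and inputs are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from . import contributions as contrib_mod
from . import correlate as corr_mod
from . import enrichment as enr_mod
from . import footprint as fp_mod
from . import io_formats as iof
from . import motif_scan as ms
from . import preprocess as pp

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage '{stage}' failed: {detail}")
        self.stage = stage


@dataclass
class PipelineConfig:
    # inputs
    atac_mtx: str = ""
    peaks_bed: str = ""
    atac_barcodes: str = ""
    fragments: str = ""
    genome_fasta: str = ""
    motifs_jaspar: str = ""
    expression_mtx: str = ""
    features: str = ""
    expr_barcodes: str = ""
    cell_types: str = ""
    metrics: str = ""
    annotation_prom: str = ""
    annotation_enhd: str = ""
    annotation_exon: str = ""
    out_dir: str = "tfmeta_out"
    # stage parameters
    qc: dict = field(default_factory=dict)               # QCConfig overrides
    scan_rel_threshold: float = 0.8
    n_background: int = 50
    enrichment_seed: Optional[int] = None                # mandatory when enrich runs
    bias_k: int = 6
    bias_enabled: bool = True
    r_threshold: float = 0.5
    p_threshold: float = 0.05
    min_overlap_bp: int = 1
    contribution_priority: tuple = contrib_mod.DEFAULT_PRIORITY
    dimer_policy: str = "drop"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def outpath(self, name: str) -> Path:
        out = Path(self.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        return out / name


def _dataset_paths(cfg: PipelineConfig, data_dir) -> PipelineConfig:
    """Point all input paths at a generated synthetic dataset directory."""
    d = Path(data_dir)
    cfg.atac_mtx = str(d / "atac_matrix.mtx")
    cfg.peaks_bed = str(d / "peaks.bed")
    cfg.atac_barcodes = str(d / "atac_barcodes.tsv")
    cfg.fragments = str(d / "fragments.tsv")
    cfg.genome_fasta = str(d / "genome.fa")
    cfg.motifs_jaspar = str(d / "motifs.jaspar")
    cfg.expression_mtx = str(d / "expression.mtx")
    cfg.features = str(d / "features.tsv")
    cfg.expr_barcodes = str(d / "expr_barcodes.tsv")
    cfg.cell_types = str(d / "cell_types.tsv")
    cfg.metrics = str(d / "metrics.tsv")
    cfg.annotation_prom = str(d / "annotation_prom.bed")
    cfg.annotation_enhd = str(d / "annotation_enhD.bed")
    cfg.annotation_exon = str(d / "annotation_exon.bed")
    return cfg


def synthetic_config(data_dir, out_dir, enrichment_seed: int = 0,
                     **overrides) -> PipelineConfig:
    """Config for a generated dataset: desk-scale gene/fragment QC bounds
    (the real-data defaults assume genome-wide feature counts)."""
    cfg = PipelineConfig(out_dir=str(out_dir), enrichment_seed=enrichment_seed,
                         qc={"min_genes": 1, "max_genes": 10**9,
                             "min_fragments": 1, "max_fragments": 10**9},
                         **overrides)
    return _dataset_paths(cfg, data_dir)


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def stage_qc(cfg: PipelineConfig) -> set[str]:
    metrics = pp.read_metrics_tsv(cfg.metrics)
    qc_cfg = pp.QCConfig(**cfg.qc)
    retained = pp.qc_filter_cells(metrics, qc_cfg)
    with open(cfg.outpath("retained_barcodes.txt"), "w") as fh:
        fh.write("".join(bc + "\n" for bc in sorted(retained)))
    logger.info("qc: retained %d / %d cells", len(retained), len(metrics))
    return retained


def stage_contributions(cfg: PipelineConfig) -> dict:
    peaks = iof.read_bed(cfg.peaks_bed)
    table = contrib_mod.label_peaks(
        peaks,
        iof.read_annotations(cfg.annotation_prom),
        iof.read_annotations(cfg.annotation_enhd),
        iof.read_annotations(cfg.annotation_exon),
        min_overlap_bp=cfg.min_overlap_bp,
        priority=cfg.contribution_priority,
    )
    contrib_mod.write_label_table(table, cfg.outpath("peak_labels.tsv"))
    return table


def _load_genome(cfg: PipelineConfig) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(cfg.genome_fasta, "fasta")}


def _load_retained_matrix(cfg: PipelineConfig, retained: set[str]) -> iof.PeakByCellMatrix:
    pbm = iof.read_peak_matrix(cfg.atac_mtx, cfg.peaks_bed, cfg.atac_barcodes)
    keep = [i for i, bc in enumerate(pbm.cells) if bc in retained]
    return iof.PeakByCellMatrix(pbm.peaks, [pbm.cells[i] for i in keep],
                                pbm.counts[:, keep])


def stage_scan(cfg: PipelineConfig, retained: set[str], labels: dict) -> dict:
    """Map motifs to expressed TF genes and build per-contribution match
    matrices; returns {'prom': (D_sub, MatchMatrix, mapped), 'enhD': ...}."""
    genome = _load_genome(cfg)
    motifs = iof.read_jaspar_pfms(cfg.motifs_jaspar)
    expr = iof.read_expression_matrix(cfg.expression_mtx, cfg.features, cfg.expr_barcodes)
    mapped = ms.map_motifs_to_genes(motifs, expr.expressed_genes(),
                                    dimer_policy=cfg.dimer_policy)
    D = _load_retained_matrix(cfg, retained)
    split = contrib_mod.split_contributions(D, labels)
    result = {}
    for tag in ("prom", "enhD"):
        D_sub = split[tag]
        mm = ms.build_match_matrix(mapped, D_sub.peaks, genome,
                                   rel_threshold=cfg.scan_rel_threshold)
        lengths = {m.id: m.length for m in mapped}
        ms.write_occurrences_bed(mm.occurrences, D_sub.peaks, lengths,
                                 cfg.outpath(f"occurrences_{tag}.bed"))
        ms.write_match_matrix(mm, cfg.outpath(f"match_{tag}.mtx"),
                              cfg.outpath(f"match_{tag}_motifs.tsv"),
                              cfg.outpath(f"match_{tag}_peaks.tsv"))
        result[tag] = (D_sub, mm, mapped)
    return result


def stage_enrich(cfg: PipelineConfig, scan_result: dict, ctmap: iof.CellTypeMap,
                 genome: dict) -> dict:
    if cfg.enrichment_seed is None:
        raise ValueError("enrichment_seed is mandatory when the enrich stage runs")
    out = {}
    for tag, (D_sub, mm, _mapped) in scan_result.items():
        cov = enr_mod.compute_covariates(D_sub, genome)
        em = enr_mod.enrichment_zscores(D_sub, mm, cov, n_background=cfg.n_background,
                                        seed=cfg.enrichment_seed, contribution=tag)
        agg = pp.aggregate_by_celltype(em.z, ctmap)
        em.z.to_csv(cfg.outpath(f"enrichment_{tag}_per_cell.tsv"), sep="\t",
                    float_format="%.6g")
        agg.to_csv(cfg.outpath(f"enrichment_{tag}_per_type.tsv"), sep="\t",
                   float_format="%.6g")
        out[tag] = agg
    return out


def stage_footprint(cfg: PipelineConfig, scan_result: dict, ctmap: iof.CellTypeMap,
                    genome: dict) -> dict:
    if not Path(cfg.fragments).exists():
        raise FileNotFoundError(f"fragments file not found: {cfg.fragments}")
    genome_codes = {c: ms.encode_sequence(s) for c, s in genome.items()}
    first = next(iter(scan_result.values()))
    cells = first[0].cells
    index = fp_mod.build_insertion_index(
        iof.read_fragments(cfg.fragments, set(cells)), cells
    )
    all_peaks = [p for tag in scan_result for p in scan_result[tag][0].peaks]
    if cfg.bias_enabled:
        bias = fp_mod.fit_bias_model(genome_codes, index, all_peaks, k=cfg.bias_k)
    else:
        bias = fp_mod.BiasModel.uniform(cfg.bias_k)
    bias_weights = {c: bias.position_weights(codes) for c, codes in genome_codes.items()}
    out = {}
    for tag, (D_sub, mm, mapped) in scan_result.items():
        res = fp_mod.footprint_matrix(mapped, D_sub, mm, index, bias_weights,
                                      ctmap, contribution=tag)
        res.per_cell.to_csv(cfg.outpath(f"footprint_{tag}_per_cell.tsv"), sep="\t",
                            float_format="%.6g")
        res.per_type.to_csv(cfg.outpath(f"footprint_{tag}_per_type.tsv"), sep="\t",
                            float_format="%.6g")
        fp_mod.write_pooled_vectors(res.pooled_vectors,
                                    cfg.outpath(f"footprint_{tag}_vectors.tsv"))
        out[tag] = res.per_type
    return out


def stage_correlate(cfg: PipelineConfig, scan_result: dict, enrich_agg: dict,
                    fp_agg: dict, ctmap: iof.CellTypeMap) -> pd.DataFrame:
    expr = iof.read_expression_matrix(cfg.expression_mtx, cfg.features, cfg.expr_barcodes)
    retained_cells = set(next(iter(scan_result.values()))[0].cells)
    keep = [i for i, bc in enumerate(expr.cells) if bc in retained_cells]
    E = pd.DataFrame(expr.values[:, keep], index=expr.genes,
                     columns=[expr.cells[i] for i in keep])
    E_agg = pp.aggregate_by_celltype(E, ctmap)
    E_agg.to_csv(cfg.outpath("expression_per_type.tsv"), sep="\t", float_format="%.6g")

    mapped = next(iter(scan_result.values()))[2]
    gene_map = {m.id: m.gene for m in mapped}
    all_records = []
    for tag in ("prom", "enhD"):
        for info_type, agg in (("enrichment", enrich_agg.get(tag)),
                               ("footprint", fp_agg.get(tag))):
            if agg is None:
                continue
            recs = corr_mod.correlate_all(E_agg, agg, gene_map, tag, info_type)
            corr_mod.records_to_frame(recs).to_csv(
                cfg.outpath(f"correlation_{tag}_{info_type}.tsv"), sep="\t",
                index=False, float_format="%.6g")
            all_records.extend(recs)
    summary = corr_mod.summarize(all_records, r_threshold=cfg.r_threshold,
                                 p_threshold=cfg.p_threshold)
    summary.table.to_csv(cfg.outpath("summary.tsv"), sep="\t", index=False,
                         float_format="%.6g")
    plot_data = corr_mod.export_plot_data(
        all_records, E_agg,
        enrich_agg=enrich_agg.get("enhD"), footprint_agg=fp_agg.get("enhD"))
    plot_data["scatter"].to_csv(cfg.outpath("scatter_enhD.tsv"), sep="\t",
                                index=False, float_format="%.6g")
    plot_data["variability"].to_csv(cfg.outpath("variability_enhD.tsv"), sep="\t",
                                    float_format="%.6g")
    return summary.table


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(cfg: PipelineConfig) -> dict:
    """Run every stage; returns the manifest dict (also written as JSON)."""
    import scipy

    def run(name, fn, *args):
        t0 = time.monotonic()
        try:
            result = fn(*args)
        except Exception as exc:
            raise StageError(name, str(exc)) from exc
        logger.info("stage %-13s done in %.1fs", name, time.monotonic() - t0)
        return result

    retained = run("qc", stage_qc, cfg)
    labels = run("contributions", stage_contributions, cfg)
    scan_result = run("scan", stage_scan, cfg, retained, labels)
    genome = _load_genome(cfg)
    retained_cells = set(next(iter(scan_result.values()))[0].cells)
    ctmap_full = iof.read_cell_type_map(cfg.cell_types)
    ctmap = iof.CellTypeMap({bc: t for bc, t in ctmap_full.mapping.items()
                             if bc in retained_cells})
    enrich_agg = run("enrich", stage_enrich, cfg, scan_result, ctmap, genome)
    fp_agg = run("footprint", stage_footprint, cfg, scan_result, ctmap, genome)
    run("correlate", stage_correlate, cfg, scan_result, enrich_agg, fp_agg, ctmap)

    out = Path(cfg.out_dir)
    inputs = {k: getattr(cfg, k) for k in
              ("atac_mtx", "peaks_bed", "atac_barcodes", "fragments", "genome_fasta",
               "motifs_jaspar", "expression_mtx", "features", "expr_barcodes",
               "cell_types", "metrics", "annotation_prom", "annotation_enhd",
               "annotation_exon")}
    manifest = {
        "inputs": {k: {"path": v, "sha256": _sha256(v)} for k, v in inputs.items() if v},
        "outputs": {p.name: _sha256(p) for p in sorted(out.iterdir())
                    if p.name != "manifest.json" and p.is_file()},
        "seeds": {"enrichment": cfg.enrichment_seed},
        "parameters": {
            "scan_rel_threshold": cfg.scan_rel_threshold,
            "n_background": cfg.n_background,
            "bias_k": cfg.bias_k, "bias_enabled": cfg.bias_enabled,
            "r_threshold": cfg.r_threshold, "p_threshold": cfg.p_threshold,
            "min_overlap_bp": cfg.min_overlap_bp,
        },
        "versions": {"numpy": np.__version__, "scipy": scipy.__version__,
                     "pandas": pd.__version__},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
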