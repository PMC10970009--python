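# tfmeta

Cross-omic transcription-factor (TF) analysis for single-cell multiome data:
do TFs' expression levels track the accessibility of their binding motifs,
and does the relationship differ between **promoter** and **distal-enhancer**
peaks?

Single-cell multiome experiments measure gene expression (scRNA-seq) and
chromatin accessibility (scATAC-seq) in the same cells, but a motif match in
an accessible peak does not mean the TF is bound or even present.  `tfmeta`
confronts three layers of evidence for every TF, split by functional peak
class and aggregated over cell types to beat single-cell sparsity:

1. **Motif enrichment** — a deviation z-score per motif `m` and cell `c`
   against GC/accessibility-matched background peak sets:
   `dev = (X_mc − E_mc)/E_mc`, `z = (dev − mean_bg)/sd_bg`, where `X_mc` sums
   counts over matched peaks and `E_mc` is the expectation under global
   per-peak count fractions (the chromVAR-style scheme).
2. **TF footprints** — bound TFs shield DNA from Tn5: per motif, the
   bias-corrected insertion signal over every occurrence ± 250 bp
   (vector length `500 + L`), summarized by the mean signal over the
   ± 50 bp flanks (the footprint score, `TFP`).
3. **Expression** — the TF gene's aggregated expression across cell types.

For each contribution (`prom`, `enhD`) and each information type
(enrichment, footprint) the pipeline reports Pearson `r` and `p` per TF
across aggregated cell types (`E[g_m, ct]` vs `ME[m, ct]` or `TFP[m, ct]`)
and the fraction of TFs with `r > 0.5, p < 0.05`.

The package is aimed at regulatory-genomics analysts who want these
statistics from standard files (MTX + BED + barcodes, 10x `fragments.tsv`,
genome FASTA, JASPAR PFMs, cell-type TSV) without a Seurat/R round-trip, and
ships a fully synthetic multiome generator with planted ground truth so
every stage is testable end to end.

## Worked example

Generate a synthetic multiome (8 cell types × 200 cells, 200 motifs with one
active cell type each, planted footprints, expression coupled to activity at
ρ = 0.9) and run the full pipeline:

```python
from tfmeta import SynthConfig, generate_dataset, run_all, synthetic_config

generate_dataset(SynthConfig(seed=1), "data/")
cfg = synthetic_config("data/", "out/", enrichment_seed=7)
run_all(cfg)
```

`out/summary.tsv` then holds the headline table (this exact run):

```
contribution   info_type  n_defined  n_passing  fraction
        enhD  enrichment        200        197      0.985
        enhD   footprint        200        121      0.605
        prom  enrichment        200        199      0.995
        prom   footprint        200        123      0.645
```

Reading: of the 200 planted-active TFs, 98–99 % show the expected strong
expression–enrichment correlation (`r > 0.5`, `p < 0.05`) in both promoter
and enhancer peaks — the planted activity is recovered.  The
expression–footprint fractions are lower by construction: footprint scores
condition on per-cell peak accessibility, which compresses the
active/inactive contrast at single-cell coverage (see `docs/methods.md`);
the planted footprint instead shows up as the footprint score ranking the
active cell type first for ~97 % of motifs
(`out/footprint_*_per_type.tsv`).

Every stage also runs from the shell:

```bash
tfmeta simulate --out data/ --seed 1
tfmeta all --config pipeline.yaml      # qc → contributions → scan →
                                       # enrich/footprint → correlate
```

Stage outputs are plain TSV/MTX/BED files (per-cell and per-cell-type
enrichment and footprint matrices, pooled footprint vectors for signal
plots, per-TF correlation records with reason codes, scatter/variability
tables) plus a `manifest.json` with input/output hashes and seeds; reruns
with the same config are byte-identical.

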