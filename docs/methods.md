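# Methods

`tfmeta` asks a single question of single-cell multiome (joint scRNA-seq +
scATAC-seq) data: **does the expression of a transcription factor (TF) track
the accessibility signal of its binding motif, and does the answer differ
between promoter and distal-enhancer peaks?**  It answers it with two
independent readouts of motif "information" — motif-enrichment deviations and
Tn5 footprint scores — computed separately per functional peak class,
aggregated per cell type, and correlated against aggregated TF expression.

## Pipeline model

### Peak contributions

scATAC peaks are labeled `prom`, `enhD` or `exon` by overlap (default ≥ 1
shared bp) with promoter / distal-enhancer / exon annotation BEDs, with the
priority order `prom > enhD > exon` for peaks overlapping several classes:
TSS-proximal peaks are dominated by promoter signal, so promoter overlap wins.
Both the minimum overlap and the priority order are configurable.  The
peak-by-cell count matrix `D` is then split row-wise into `D_prom`, `D_enhD`,
`D_exon`; every downstream statistic is computed on `D_prom` and `D_enhD`
independently and never mixes rows across classes.

### Motif scanning

JASPAR PFMs are converted to log2-odds PWMs with a pseudocount of 0.8
distributed by the background composition (default uniform):
`score(b, j) = log2(((pfm[b,j] + 0.8·bg_b) / (colsum_j + 0.8)) / bg_b)`.
A window is a match when its score reaches
`min + rel_threshold · (max − min)` with `rel_threshold = 0.8` by default — a
relative-score cut in the style of common motif-match tools, chosen over a
p-value threshold to avoid estimating a null score distribution; the knob is
exposed because reasonable analyses use 0.75–0.9.  Both strands are scanned
(the reverse strand scores the reverse complement); windows containing `N`
are skipped.  Only motifs whose TF gene is expressed (nonzero total count,
case-insensitive symbol match) are analyzed; heterodimer entries
(`FOS::JUN`) are dropped by default, or kept when every subunit is expressed
under the `require_all` policy.

### Motif-enrichment deviations

The enrichment of motif `m` in cell `c` follows the bias-corrected deviation
z-score scheme popularized by chromVAR.  With `f_p` the global fraction of
counts in peak `p` (so `Σ f_p = 1`):

    X_mc = Σ_{p ∈ match(m)} D[p, c]
    E_mc = (Σ_{p ∈ match(m)} f_p) · Σ_p D[p, c]
    dev_mc = (X_mc − E_mc) / E_mc

The raw deviation is standardized against `n_background = 50` background peak
sets: each matched peak is replaced by one of its `k = 50` nearest neighbors
(with replacement, self allowed) in standardized
`(GC fraction, log1p mean accessibility)` space, and
`z = (dev − mean_bg) / sd_bg`.  Background sampling is seeded and the seed is
mandatory in pipeline configs.  Degenerate cases are reported missing rather
than propagated: background `sd = 0`, motifs with no matched peak, and motifs
matching *every* peak (raw deviation identically zero, so z is 0/0).  When
all covariates are identical the neighborhood degenerates to the whole peak
set, i.e. uniform background sampling.

### Tn5 footprints

Every fragment contributes two insertions, at `start` and `end − 1`
(10x fragment coordinates are already Tn5-shifted; no further +4/−5 shift is
applied).  For each motif occurrence the window spans the motif ± 250 bp, so
a footprint vector has length `n = 500 + L` exactly.  Windows of `−` strand
occurrences are reversed before averaging so flanks align biologically.
Per-base counts are divided by a sequence-bias weight: the observed/expected
frequency of the k-mer (default hexamer, `k = 6`) centered on the insertion —
centered meaning the k-mer spans `[pos − k//2, pos − k//2 + k)` — with
background frequencies from the peak sequences, floored at ε = 1e−3.  Below
1000 in-peak insertions the model falls back to uniform weights (all exactly
1, so corrected ≡ raw).  The occurrence-averaged vector is depth-normalized
to insertions-per-million within the contribution's peaks for the scope.

The footprint score is the mean signal over the 50 bp immediately flanking
the motif on each side (positions 201–250 and 251+L–300+L, 1-based; the
motif-adjacent base is included, the motif itself is not).  Scores are
computed per cell literally — scope = one cell, occurrences restricted to
peaks with ≥ 1 count in that cell, missing when the cell has no in-scope
insertion — and averaged per cell type ignoring missing values; pooled
per-cell-type vectors (scope = all cells of the type) are exported separately
for signal plots, because per-cell footprints are extremely sparse.
Depth normalization is applied after occurrence-averaging.

### QC and aggregation

Cell QC bounds are inclusive: retained iff
`200 ≤ genes ≤ 2500`, `mito ≤ 5 %`, `3000 ≤ fragments ≤ 30000` (defaults for
genome-scale 10x data; synthetic desk-scale runs set their own bounds).
Nucleosome-signal and TSS-enrichment predicates exist but have no default
thresholds and are disabled unless configured.  Aggregation is the
unweighted arithmetic mean over a cell type's cells, ignoring missing
values, with columns in sorted label order; it is linear and invariant to
cell order.

### Correlation

For each mapped motif, Pearson r between the TF gene's aggregated expression
and the motif's aggregated information row, per contribution and information
type.  p is two-sided from `t = r·sqrt((n−2)/(1−r²))` on `n − 2` df; missing
values are removed pairwise and `n_ct` recorded; `n < 3` or zero variance
yields a record with a reason code instead of numbers.  The headline summary
is the fraction of TFs with `r > 0.5` and raw `p < 0.05` (no multiplicity
correction; a Benjamini–Hochberg column is exported alongside but not used).
With ~8 cell types these p-values are low-power — at `n = 8`, `p < 0.05`
requires `|r| > 0.707` — and should be read as descriptive.

## The synthetic multiome

The generator builds the complete input set — genome FASTA, disjoint peaks,
JASPAR PFMs, fragments, ATAC and expression matrices, cell-type labels,
annotation BEDs, QC metrics — with planted ground truth, so every stage can
be scored against what was put in.

**Study conditions (defaults).**  8 cell types × 200 cells; 200 motifs of
length 12 with one active cell type each (activity 1, one-hot, round-robin);
850 promoter + 850 enhancer peaks of 500 bp (plus 60 exon / 40 unlabeled),
each motif planted in 4 promoter and 4 enhancer peaks with per-base
substitution probability 0.05; Poisson fragment counts with intensity
∝ `base_accessibility (0.5) + activity`; planted footprints with depth 0.7
(70 % depletion inside bound motifs) and flank boost 1.5 within ± 50 bp;
expression = activity + Gaussian noise calibrated so the aggregated
expression–activity Pearson correlation is 0.9 in expectation.

**Design choices and why.**

* *One motif per peak (exclusive planting).*  If peaks carry several motifs
  with independent one-hot activities, the co-residents' activities add
  cell-type-structured variance to every motif's count profile
  (≈ `n_plants·(d−1)/T` against a signal variance of `n_plants²·var(a)` for
  `d` motifs/peak and `T` types), capping the enrichment–activity
  correlation well below what the expression side (ρ = 0.9) needs for
  recovery to be observable.  With exclusive planting the only noise left is
  Poisson counting noise, and the insertion rate (1e−3 per bp per cell per
  unit intensity, ≈ 100 fragments per motif-class-type) keeps that term
  small.  This is an intentional idealization: real peaks host multiple
  motifs and real TF activities are correlated.
* *Motif construction.*  Consensus sequences are drawn randomly but kept at
  pairwise Hamming distance ≥ 4 at every full-containment alignment on both
  strands (greedy single-base repair), and at distance ≥ 4 from their own
  reverse complement; with the sharp PFM (consensus count 85 against 6/5/4)
  and the 0.8 scan threshold a match tolerates exactly 2 mismatches, so
  plants of one motif cannot match another and ≈ 98 % of plants
  (`P(Binom(12, 0.05) ≤ 2)`) are recoverable.
* *Background scrubbing.*  A uniform random genome contains chance matches
  (~2-mismatch 12-mers) at a rate far above 5 % of plants, so after planting
  the generator rescans and mutates background bases inside spurious match
  windows until none remain, choosing among the two lowest-scoring bases at
  random (a deterministic anti-consensus choice can oscillate between
  competing motifs).  Bases inside planted intervals are never touched; a
  window whose score rests on another motif's plant is therefore unremovable
  and is counted in `GroundTruth.unscrubbed_matches` (≈ 1 % of plants at
  default scale).
* *Monotone count coupling.*  ATAC counts are drawn by inverse-CDF Poisson
  (`poisson.ppf` on a dedicated uniform stream), so raising one activity
  entry at fixed seed can only raise the affected counts — a property the
  test suite checks directly and `rng.poisson` would not provide.
* *Insertion profile.*  Fragment endpoints are drawn i.i.d. from a per-base
  profile that is uniform except at bound motifs (activity > 0.5), where the
  interior is multiplied by `1 − depth` and the ±50 bp flanks by the boost;
  an optional center-base preference (`center_base_bias`) plants a Tn5
  sequence bias for exercising the bias model.
* *Expression calibration.*  For target correlation ρ, per-cell noise
  σ = `sqrt(cells_per_type · var(a) · (1/ρ² − 1))` makes the aggregated
  (per-type mean) correlation ρ in expectation; ρ = ±1 is exact (no noise),
  ρ = 0 is pure noise.  Values are clipped at 0 (rare) and flagged
  normalized, not counts.

**What the generator does not emulate** — and hence what green tests do not
establish about real data: overlapping or variable-width peaks, genome
sequence composition beyond a single GC fraction, correlated TF activities
and co-binding, doublets, batch effects, mitochondrial reads (QC metrics are
emitted directly), PCR duplication (fragment counts are 1), peak–gene
regulatory structure, and realistic library-size variation.

## Interpreting the recovery numbers

At the study conditions, ≈ 99 % of TFs pass `r > 0.5, p < 0.05` for
expression vs *enrichment*, but only ~60 % for expression vs *footprint
score*.  The latter is a property of the footprint definition at single-cell
coverage, not an implementation artifact: occurrences are restricted to
peaks accessible in the cell (count ≥ 1), and conditioning on `count ≥ 1`
compresses the active/inactive intensity contrast (E[count | count ≥ 1]
approaches 1 as coverage drops), capping the across-type correlation near
0.75 before the expression noise multiplies in.  The planted footprint is
instead verified by ordering: the footprint score is highest in the planted
active cell type for ≈ 97 % of motifs, and pooled per-type vectors show the
depleted-core/elevated-flank shape.

## Problem sizes

The test suite exercises most modules on a small multiome (4 types × 20
cells, 20 motifs, 88 peaks) and the recovery properties on the full study
conditions (8 × 200 cells, 200 motifs, 1800 peaks, ≈ 430k fragments); the
acceptance script regenerates the study-scale dataset from scratch, runs the
full pipeline, and recomputes every reported quantity.  End-to-end
determinism (byte-identical reruns) is asserted at the small scale.

## Known limitations

* Per-cell footprint scores are missing for cells with no in-scope
  insertions; at low coverage the per-type mean rests on a minority of
  cells.
* Background-matched z-scores depend on the background seed; `n_background`
  = 50 leaves a few percent Monte-Carlo noise in z.
* The correlation stage assumes one gene symbol per motif; motifs whose TF
  maps to multiple genes (beyond `::` dimers) are not resolved.
* Peak labeling is overlap-based only; no TSS-proximity or co-accessibility
  linking of peaks to genes is performed.
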