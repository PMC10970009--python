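"""Synthetic multiome generator with planted transcription-factor activity.

Emits a complete toy dataset — genome FASTA, disjoint peaks, JASPAR PFMs,
10x-style fragments, ATAC and expression count matrices, cell-type labels,
per-class annotation BEDs and a QC metrics table — in exactly the formats
the reader module consumes, together with the ground truth needed to score
every downstream stage.

Generative model
----------------
* Each motif is a sharp-consensus PFM; its consensus is planted (per-base
  substitution probability 0.05) into a configured number of promoter and
  distal-enhancer peaks, at most one motif per peak so each peak's
  accessibility is driven by a single TF.  Consensus sequences are kept
  mutually distant (Hamming >= 4 at every full-containment alignment, both
  strands) and the background sequence is scrubbed of chance matches, so
  scanning at the default threshold recovers plants cleanly.
* Cell ``c`` of type ``t`` sees peak ``p`` with fragment intensity
  proportional to ``base_accessibility + sum of activity[m, t]`` over the
  motifs planted in ``p``; per-(peak, cell) fragment counts are Poisson,
  sampled by inverse CDF from a dedicated uniform stream so that raising an
  activity entry can never lower a count at fixed seed.
* Fragment endpoints are drawn from a per-base insertion profile that is
  uniform except at bound motifs (activity > 0.5): the motif interior is
  depleted by ``1 - footprint_depth`` and the +/-50 bp flanks are boosted by
  ``flank_boost`` — a planted Tn5 footprint.
* The TF gene of motif ``m`` is expressed as an affine function of
  ``activity[m, t]`` plus Gaussian noise calibrated so that the
  across-cell-type Pearson correlation with activity is
  ``expr_activity_rho`` in expectation; filler genes are pure noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

from . import io_formats as iof
from . import motif_scan as ms

_CLASS_CHROMS = {"prom": "chr_prom", "enhD": "chr_enhd", "exon": "chr_exon", "none": "chr_none"}
_PEAK_GAP = 400          # >= 300 bp so +/-250 bp footprint windows never cross peaks
_CONSENSUS_COUNT = 85    # PFM count of the consensus base
_OFF_COUNTS = (6, 5, 4)  # PFM counts of the three other bases (unequal: breaks score ties)
_MIN_CROSS_DISTANCE = 4  # min Hamming distance between consensi at containment alignments


@dataclass
class SynthConfig:
    """Study conditions for the synthetic multiome."""

    seed: int = 0
    n_cell_types: int = 8
    cells_per_type: int = 200
    n_peaks_per_class: dict = field(
        default_factory=lambda: {"prom": 850, "enhD": 850, "exon": 60, "none": 40}
    )
    peak_length: int = 500
    n_motifs: int = 200
    motif_length_range: tuple = (12, 12)
    # activity[m, t] in [0, 1]; None -> one active cell type per motif (round robin)
    activity: Optional[np.ndarray] = None
    expr_activity_rho: float = 0.9
    footprint_depth: float = 0.7
    flank_boost: float = 1.5
    baseline_insertion_rate: float = 1e-3   # insertions per bp per cell at unit intensity
    base_accessibility: float = 0.5         # intensity floor shared by every peak
    gc_content: float = 0.41
    plants_per_class: dict = field(default_factory=lambda: {"prom": 4, "enhD": 4})
    substitution_prob: float = 0.05
    # per-motif planting restriction: "both" | "prom" | "enhD" (None -> all "both")
    motif_peak_classes: Optional[list] = None
    center_base_bias: Optional[dict] = None  # e.g. {"A": 2.0}: planted Tn5 sequence bias
    n_filler_genes: int = 50
    expr_baseline: float = 5.0
    scan_rel_threshold: float = 0.8          # threshold the scrubber protects against

    def __post_init__(self):
        if not 0 < self.gc_content < 1:
            raise ValueError("gc_content must be in (0, 1)")
        if not -1 <= self.expr_activity_rho <= 1:
            raise ValueError("expr_activity_rho must be in [-1, 1]")
        if not 0 <= self.footprint_depth <= 1:
            raise ValueError("footprint_depth must be in [0, 1]")
        if self.flank_boost < 1:
            raise ValueError("flank_boost must be >= 1")
        if self.motif_length_range[0] > self.motif_length_range[1]:
            raise ValueError("bad motif_length_range")
        if self.activity is not None:
            self.activity = np.asarray(self.activity, dtype=float)
            if self.activity.shape != (self.n_motifs, self.n_cell_types):
                raise ValueError(
                    f"activity shape {self.activity.shape} != "
                    f"({self.n_motifs}, {self.n_cell_types})"
                )
            if self.activity.min() < 0 or self.activity.max() > 1:
                raise ValueError("activity entries must lie in [0, 1]")


@dataclass(frozen=True)
class PlantedOccurrence:
    motif_id: str
    peak_id: str
    offset: int
    strand: str


@dataclass
class GroundTruth:
    """Everything needed to score the pipeline against the generator."""

    motifs: list                      # list of io_formats.Motif
    occurrences: list                 # list of PlantedOccurrence
    activity: pd.DataFrame            # motifs x cell types
    expected_expr_rho: float
    peak_classes: dict                # peak id -> class label
    peaks: list                       # list of PeakRegion
    cell_types: dict                  # barcode -> type label
    unplaceable_plants: int = 0       # plant requests skipped for lack of room
    unscrubbed_matches: int = 0       # chance matches resting on planted bases

    def occurrences_for(self, motif_id: str) -> list[PlantedOccurrence]:
        return [o for o in self.occurrences if o.motif_id == motif_id]

    def active_types(self, motif_id: str, threshold: float = 0.5) -> list[str]:
        row = self.activity.loc[motif_id]
        return [ct for ct in row.index if row[ct] > threshold]


# ---------------------------------------------------------------------------
# Motif construction
# ---------------------------------------------------------------------------

def _hamming(a: np.ndarray, b: np.ndarray) -> int:
    return int((a != b).sum())


def _revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return (3 - codes)[::-1]


def _min_containment_distance(a: np.ndarray, b: np.ndarray) -> int:
    """Min Hamming distance of the shorter sequence against every window of
    the longer one (both orientations of the longer)."""
    short, long_ = (a, b) if len(a) <= len(b) else (b, a)
    best = len(short)
    for target in (long_, _revcomp_codes(long_)):
        for off in range(len(target) - len(short) + 1):
            best = min(best, _hamming(short, target[off:off + len(short)]))
    return best


def _violations(cand: np.ndarray, consensi: list) -> int:
    v = 0
    if _hamming(cand, _revcomp_codes(cand)) < _MIN_CROSS_DISTANCE:
        v += 1
    for prev in consensi:
        if _min_containment_distance(cand, prev) < _MIN_CROSS_DISTANCE:
            v += 1
    return v


def _draw_consensi(rng: np.random.Generator, cfg: SynthConfig) -> list[np.ndarray]:
    """Random consensi kept mutually distant (greedy single-base repair)."""
    lmin, lmax = cfg.motif_length_range
    consensi: list[np.ndarray] = []
    for _ in range(cfg.n_motifs):
        placed = False
        for _fresh in range(50):
            L = int(rng.integers(lmin, lmax + 1))
            cand = rng.integers(0, 4, size=L)
            v = _violations(cand, consensi)
            for _step in range(4 * L):
                if v == 0:
                    break
                # greedy: the single-base change removing the most violations
                best = (v, None)
                for j in rng.permutation(L):
                    orig = cand[j]
                    for b in range(4):
                        if b == orig:
                            continue
                        cand[j] = b
                        vv = _violations(cand, consensi)
                        if vv < best[0]:
                            best = (vv, (j, b))
                    cand[j] = orig
                if best[1] is None:
                    break
                j, b = best[1]
                cand[j] = b
                v = best[0]
            if v == 0:
                consensi.append(cand)
                placed = True
                break
        if not placed:
            raise RuntimeError("could not construct mutually distant motif consensi")
    return consensi


def _consensus_to_motif(codes: np.ndarray, idx: int, rng: np.random.Generator) -> iof.Motif:
    L = len(codes)
    pfm = np.zeros((4, L))
    for j, c in enumerate(codes):
        off = list(_OFF_COUNTS)
        rng.shuffle(off)
        others = [b for b in range(4) if b != c]
        pfm[c, j] = _CONSENSUS_COUNT
        for b, cnt in zip(others, off):
            pfm[b, j] = cnt
    return iof.Motif(id=f"SM{idx + 1:04d}.1", name=f"TF{idx + 1:03d}", pfm=pfm)


# ---------------------------------------------------------------------------
# Genome and planting
# ---------------------------------------------------------------------------

def _random_genome(rng: np.random.Generator, cfg: SynthConfig) -> tuple[dict, list, dict]:
    """Build per-class chromosomes of random sequence plus disjoint peaks."""
    probs = np.array([(1 - cfg.gc_content) / 2, cfg.gc_content / 2,
                      cfg.gc_content / 2, (1 - cfg.gc_content) / 2])
    genome_codes, peaks, peak_classes = {}, [], {}
    pidx = 0
    for cls, chrom in _CLASS_CHROMS.items():
        n = cfg.n_peaks_per_class.get(cls, 0)
        if n == 0:
            continue
        length = _PEAK_GAP + n * (cfg.peak_length + _PEAK_GAP)
        genome_codes[chrom] = rng.choice(4, size=length, p=probs).astype(np.int8)
        for i in range(n):
            start = _PEAK_GAP + i * (cfg.peak_length + _PEAK_GAP)
            pidx += 1
            peak = iof.PeakRegion(chrom, start, start + cfg.peak_length, f"peak{pidx:05d}")
            peaks.append(peak)
            peak_classes[peak.id] = cls
    return genome_codes, peaks, peak_classes


def _plant_motifs(rng: np.random.Generator, cfg: SynthConfig, motifs: list,
                  consensi: list, genome_codes: dict, peaks: list,
                  peak_classes: dict) -> tuple[list, int]:
    """Exclusive planting: every prom/enhD peak hosts at most one motif.

    One motif per peak keeps each peak's accessibility driven by a single
    TF's activity, so planted activity is identifiable downstream.
    """
    classes = cfg.motif_peak_classes or ["both"] * cfg.n_motifs
    pools = {}
    for cls in ("prom", "enhD"):
        pool = [p for p in peaks if peak_classes[p.id] == cls]
        order = rng.permutation(len(pool))
        pools[cls] = [pool[int(i)] for i in order]
    cursor = {"prom": 0, "enhD": 0}
    occurrences, skipped = [], 0
    for m, codes, mcls in zip(motifs, consensi, classes):
        L = len(codes)
        for cls in ("prom", "enhD"):
            if mcls not in ("both", cls):
                continue
            n_plants = int(cfg.plants_per_class.get(cls, 0))
            for _ in range(n_plants):
                if cursor[cls] >= len(pools[cls]):
                    raise ValueError(
                        f"not enough {cls} peaks for exclusive planting: need "
                        f"more than {len(pools[cls])}"
                    )
                peak = pools[cls][cursor[cls]]
                cursor[cls] += 1
                offset = int(rng.integers(0, cfg.peak_length - L + 1))
                strand = "+" if rng.random() < 0.5 else "-"
                planted = codes.copy()
                subs = rng.random(L) < cfg.substitution_prob
                for j in np.flatnonzero(subs):
                    planted[j] = (planted[j] + rng.integers(1, 4)) % 4
                if strand == "-":
                    planted = _revcomp_codes(planted)
                genome_codes[peak.chrom][peak.start + offset: peak.start + offset + L] = planted
                occurrences.append(PlantedOccurrence(m.id, peak.id, offset, strand))
    return occurrences, skipped


def _scrub_background(rng: np.random.Generator, cfg: SynthConfig, motifs: list,
                      genome_codes: dict, peaks: list, occurrences: list,
                      max_rounds: int = 30) -> int:
    """Remove chance motif matches from the generated sequence.

    Repeated scan-and-mutate rounds: each spurious window has its
    highest-contribution background bases pushed to low-scoring bases until
    it must fall below the scan threshold.  The replacement base is chosen
    at random between the two lowest-scoring bases of the column — a
    deterministic anti-consensus choice can oscillate when it completes a
    window of another motif.  Bases inside planted intervals are never
    touched, so a window whose score rests on a plant of another motif is
    unfixable and stays (the count of such windows is returned).  After the
    first round only mutated peaks are rescanned.
    """
    planted_pos = {(o.peak_id, o.offset) for o in occurrences}
    lengths = {m.id: m.length for m in motifs}
    planted_intervals: dict[str, list] = {}
    for o in occurrences:
        planted_intervals.setdefault(o.peak_id, []).append(
            (o.offset, o.offset + lengths[o.motif_id]))

    peak_by_id = {p.id: p for p in peaks}
    pwms = {m.id: ms.pfm_to_pwm(m) for m in motifs}
    scan_peaks = list(peaks)                 # round 1 scans everything
    unfixable_peaks: set[str] = set()
    for round_no in range(max_rounds):
        if round_no == 0:
            genome_str = {c: _codes_to_str(v) for c, v in genome_codes.items()}
            query_peaks = scan_peaks
        else:
            genome_str = {
                p.id: _codes_to_str(genome_codes[p.chrom][p.start:p.end])
                for p in scan_peaks
            }
            query_peaks = [iof.PeakRegion(p.id, 0, len(p), p.id) for p in scan_peaks]
        mm = ms.build_match_matrix(motifs, query_peaks, genome_str,
                                   rel_threshold=cfg.scan_rel_threshold)
        touched: set[str] = set()
        for occ in mm.occurrences:
            if (occ.peak_id, occ.offset) in planted_pos:
                continue
            L = lengths[occ.motif_id]
            blocked = planted_intervals.get(occ.peak_id, [])
            peak = peak_by_id[occ.peak_id]
            pwm = pwms[occ.motif_id]
            mat = pwm.matrix if occ.strand == "+" else pwm.matrix[::-1, ::-1]
            need = occ.score - pwm.threshold(cfg.scan_rel_threshold)
            options = []
            max_reduction = 0.0
            for j in range(occ.offset, occ.offset + L):
                if any(s <= j < e for s, e in blocked):
                    continue
                col = j - occ.offset
                cur_base = int(genome_codes[peak.chrom][peak.start + j])
                order = np.argsort(mat[:, col])
                b_new = int(order[int(rng.integers(0, 2))])   # one of two lowest
                reduction = float(mat[cur_base, col] - mat[b_new, col])
                options.append((reduction, j, b_new))
                max_reduction += float(mat[cur_base, col] - mat[int(order[0]), col])
            if max_reduction <= need:
                unfixable_peaks.add(occ.peak_id)   # plant bases keep it matching
                continue
            options.sort(reverse=True)
            removed = 0.0
            for reduction, j, b_new in options:
                if removed > need:
                    break
                genome_codes[peak.chrom][peak.start + j] = b_new
                removed += reduction
            touched.add(occ.peak_id)
        if not touched:
            break
        scan_peaks = [peak_by_id[pid] for pid in sorted(touched)]

    # final accounting over every peak that ever hosted an unfixable window
    if not unfixable_peaks:
        return 0
    check = [peak_by_id[pid] for pid in sorted(unfixable_peaks)]
    genome_str = {
        p.id: _codes_to_str(genome_codes[p.chrom][p.start:p.end]) for p in check
    }
    query = [iof.PeakRegion(p.id, 0, len(p), p.id) for p in check]
    mm = ms.build_match_matrix(motifs, query, genome_str,
                               rel_threshold=cfg.scan_rel_threshold)
    return sum(1 for o in mm.occurrences
               if (o.peak_id, o.offset) not in planted_pos)


def _codes_to_str(codes: np.ndarray) -> str:
    return "".join(np.array(list("ACGT"))[codes])


# ---------------------------------------------------------------------------
# Counts, fragments, expression
# ---------------------------------------------------------------------------

def _peak_intensity(cfg: SynthConfig, activity: np.ndarray, motifs: list,
                    occurrences: list, peaks: list) -> np.ndarray:
    """Per (peak, cell type) fragment intensity lambda."""
    midx = {m.id: i for i, m in enumerate(motifs)}
    pidx = {p.id: i for i, p in enumerate(peaks)}
    S = np.zeros((len(peaks), cfg.n_cell_types))
    seen = set()
    for o in occurrences:
        key = (o.peak_id, o.motif_id)
        if key in seen:                       # a motif counts once per peak
            continue
        seen.add(key)
        S[pidx[o.peak_id], :] += activity[midx[o.motif_id], :]
    return 0.5 * cfg.peak_length * cfg.baseline_insertion_rate * (cfg.base_accessibility + S)


def sample_fragment_counts(cfg: SynthConfig, lam: np.ndarray,
                           uniforms: np.ndarray, type_of_cell: np.ndarray) -> np.ndarray:
    """Inverse-CDF Poisson counts: monotone in lambda at fixed uniforms."""
    lam_pc = lam[:, type_of_cell]
    with np.errstate(divide="ignore", invalid="ignore"):
        counts = stats.poisson.ppf(uniforms, lam_pc)
    return np.nan_to_num(counts, nan=0.0).astype(np.int64)


def _insertion_profile(cfg: SynthConfig, peak, peak_class, occ_in_peak, activity_col,
                       midx, genome_codes) -> np.ndarray:
    """Per-base insertion weight inside one peak for one cell type."""
    w = np.ones(cfg.peak_length)
    for o, L in occ_in_peak:
        if activity_col[midx[o.motif_id]] <= 0.5:
            continue
        lo, hi = o.offset, o.offset + L
        w[lo:hi] *= (1.0 - cfg.footprint_depth)
        w[max(0, lo - 50):lo] *= cfg.flank_boost
        w[hi:min(cfg.peak_length, hi + 50)] *= cfg.flank_boost
    if cfg.center_base_bias:
        codes = genome_codes[peak.chrom][peak.start:peak.end]
        mult = np.ones(4)
        for base, factor in cfg.center_base_bias.items():
            mult["ACGT".index(base)] = factor
        w *= mult[codes]
    total = w.sum()
    if total <= 0:
        w = np.ones(cfg.peak_length)
        total = w.sum()
    return w / total


def _make_fragments(rng: np.random.Generator, cfg: SynthConfig, motifs, occurrences,
                    peaks, peak_classes, counts, barcodes, type_of_cell,
                    genome_codes) -> list:
    midx = {m.id: i for i, m in enumerate(motifs)}
    lengths = {m.id: m.length for m in motifs}
    occ_by_peak: dict[str, list] = {}
    for o in occurrences:
        occ_by_peak.setdefault(o.peak_id, []).append((o, lengths[o.motif_id]))
    fragments = []
    for pi, peak in enumerate(peaks):
        row = counts[pi]
        for t in range(cfg.n_cell_types):
            cell_idx = np.flatnonzero(type_of_cell == t)
            n_per_cell = row[cell_idx]
            total = int(n_per_cell.sum())
            if total == 0:
                continue
            profile = _insertion_profile(
                cfg, peak, peak_classes[peak.id], occ_by_peak.get(peak.id, []),
                _activity_col(cfg, t), midx, genome_codes,
            )
            pos = rng.choice(cfg.peak_length, size=2 * total, p=profile)
            pos = np.sort(pos.reshape(total, 2), axis=1)
            same = pos[:, 0] == pos[:, 1]
            pos[same, 1] = np.minimum(pos[same, 0] + 1, cfg.peak_length - 1)
            pos[same, 0] = np.minimum(pos[same, 0], pos[same, 1] - 1)
            owner = np.repeat(cell_idx, n_per_cell)
            for (a, b), ci in zip(pos, owner):
                fragments.append(iof.Fragment(
                    peak.chrom, int(peak.start + a), int(peak.start + b + 1),
                    barcodes[int(ci)], 1,
                ))
    fragments.sort(key=lambda f: (f.chrom, f.start, f.end, f.barcode))
    return fragments


def _activity_col(cfg: SynthConfig, t: int) -> np.ndarray:
    return cfg.activity[:, t]


def default_activity(cfg: SynthConfig) -> np.ndarray:
    """One active cell type per motif (round robin), activity 1 there, 0 elsewhere."""
    A = np.zeros((cfg.n_motifs, cfg.n_cell_types))
    for m in range(cfg.n_motifs):
        A[m, m % cfg.n_cell_types] = 1.0
    return A


def generate_expression(rng: np.random.Generator, cfg: SynthConfig, activity: np.ndarray,
                        barcodes: list, type_of_cell: np.ndarray,
                        motifs: list) -> iof.ExpressionMatrix:
    """TF-gene expression = affine(activity) + noise calibrated so the
    aggregated (per-cell-type mean) correlation with activity is
    ``expr_activity_rho`` in expectation; filler genes are pure noise."""
    rho = cfg.expr_activity_rho
    n_cells = len(barcodes)
    rows, genes = [], []
    for i, m in enumerate(motifs):
        a = activity[i, type_of_cell]
        var_a = float(np.var(activity[i, :]))
        if rho == 0 or var_a == 0:
            e = cfg.expr_baseline + rng.normal(0.0, 1.0, n_cells)
        elif abs(rho) == 1:
            e = cfg.expr_baseline + np.sign(rho) * a
        else:
            sigma = np.sqrt(cfg.cells_per_type * var_a * (1.0 / rho**2 - 1.0))
            e = cfg.expr_baseline + np.sign(rho) * a + rng.normal(0.0, sigma, n_cells)
        rows.append(np.maximum(e, 0.0))
        genes.append(m.name)
    for j in range(cfg.n_filler_genes):
        rows.append(np.abs(rng.normal(3.0, 1.0, n_cells)))
        genes.append(f"FILLER{j + 1:03d}")
    return iof.ExpressionMatrix(genes, list(barcodes), np.vstack(rows), normalized=True)


# ---------------------------------------------------------------------------
# Top-level generation
# ---------------------------------------------------------------------------

def generate_dataset(config: SynthConfig, out_dir) -> GroundTruth:
    """Generate and write the full synthetic multiome; deterministic in seed."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    streams = np.random.SeedSequence(config.seed).spawn(8)
    rng_genome, rng_motifs, rng_plant, rng_scrub, rng_counts, rng_frag, rng_expr, rng_metrics = (
        np.random.default_rng(s) for s in streams
    )

    if config.activity is None:
        config.activity = default_activity(config)
    activity = config.activity

    consensi = _draw_consensi(rng_motifs, config)
    motifs = [_consensus_to_motif(c, i, rng_motifs) for i, c in enumerate(consensi)]

    genome_codes, peaks, peak_classes = _random_genome(rng_genome, config)
    occurrences, skipped = _plant_motifs(
        rng_plant, config, motifs, consensi, genome_codes, peaks, peak_classes
    )
    n_unscrubbed = _scrub_background(rng_scrub, config, motifs, genome_codes,
                                     peaks, occurrences)

    # cells
    type_labels = [f"CT{t + 1:02d}" for t in range(config.n_cell_types)]
    barcodes, type_of_cell = [], []
    for t in range(config.n_cell_types):
        for c in range(config.cells_per_type):
            barcodes.append(f"BC{t + 1:02d}_{c + 1:04d}")
            type_of_cell.append(t)
    type_of_cell = np.array(type_of_cell)

    # ATAC counts (inverse-CDF Poisson for monotone coupling in activity)
    lam = _peak_intensity(config, activity, motifs, occurrences, peaks)
    uniforms = rng_counts.random((len(peaks), len(barcodes)))
    counts = sample_fragment_counts(config, lam, uniforms, type_of_cell)

    fragments = _make_fragments(rng_frag, config, motifs, occurrences, peaks,
                                peak_classes, counts, barcodes, type_of_cell, genome_codes)

    expression = generate_expression(rng_expr, config, activity, barcodes,
                                     type_of_cell, motifs)

    # ---- write everything -------------------------------------------------
    with open(out / "genome.fa", "w") as fh:
        for chrom in sorted(genome_codes):
            fh.write(f">{chrom}\n")
            seq = _codes_to_str(genome_codes[chrom])
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")

    pbm = iof.PeakByCellMatrix(peaks, barcodes, sp.csr_matrix(counts))
    iof.write_peak_matrix(pbm, out / "atac_matrix.mtx", out / "peaks.bed",
                          out / "atac_barcodes.tsv")
    iof.write_fragments(fragments, out / "fragments.tsv")
    iof.write_jaspar_pfms(motifs, out / "motifs.jaspar")
    iof.write_expression_matrix(expression, out / "expression.mtx",
                                out / "features.tsv", out / "expr_barcodes.tsv")

    ctmap = iof.CellTypeMap({bc: type_labels[t] for bc, t in zip(barcodes, type_of_cell)})
    iof.write_cell_type_map(ctmap, out / "cell_types.tsv")

    for cls in ("prom", "enhD", "exon"):
        regions = [p for p in peaks if peak_classes[p.id] == cls]
        iof.write_bed(regions, out / f"annotation_{cls}.bed")

    n_frag_per_cell = np.zeros(len(barcodes), dtype=int)
    bc_index = {bc: i for i, bc in enumerate(barcodes)}
    for f in fragments:
        n_frag_per_cell[bc_index[f.barcode]] += 1
    n_genes_per_cell = (expression.values > 0).sum(axis=0)
    mito = rng_metrics.uniform(0.0, 5.0, len(barcodes))
    with open(out / "metrics.tsv", "w") as fh:
        fh.write("barcode\tn_unique_genes\tmito_pct\tn_fragments\n")
        for i, bc in enumerate(barcodes):
            fh.write(f"{bc}\t{n_genes_per_cell[i]}\t{mito[i]:.4f}\t{n_frag_per_cell[i]}\n")

    gt = GroundTruth(
        motifs=motifs,
        occurrences=occurrences,
        activity=pd.DataFrame(activity, index=[m.id for m in motifs], columns=type_labels),
        expected_expr_rho=config.expr_activity_rho,
        peak_classes=peak_classes,
        peaks=peaks,
        cell_types=dict(ctmap.mapping),
        unplaceable_plants=skipped,
        unscrubbed_matches=n_unscrubbed,
    )
    truth_report(gt).to_csv(out / "truth_motifs.tsv", sep="\t")
    with open(out / "truth_occurrences.tsv", "w") as fh:
        fh.write("motif_id\tpeak_id\toffset\tstrand\n")
        for o in occurrences:
            fh.write(f"{o.motif_id}\t{o.peak_id}\t{o.offset}\t{o.strand}\n")
    return gt


def truth_report(gt: GroundTruth) -> pd.DataFrame:
    """Per-motif summary: plants per class, max activity, active cell types."""
    rows = {}
    for m in gt.motifs:
        per_class = {"prom": 0, "enhD": 0, "exon": 0}
        for o in gt.occurrences_for(m.id):
            per_class[gt.peak_classes[o.peak_id]] += 1
        act = gt.activity.loc[m.id]
        rows[m.id] = {
            "name": m.name,
            "n_prom": per_class["prom"],
            "n_enhD": per_class["enhD"],
            "n_exon": per_class["exon"],
            "max_activity": float(act.max()),
            "active_cell_types": ",".join(gt.active_types(m.id)),
        }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "motif_id"
    return df
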