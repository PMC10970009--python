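"""TF footprinting from Tn5 insertion events.

Each sequenced fragment marks two insertions (its start and ``end - 1``).
For a motif, the per-base insertion signal over every occurrence window
(motif +/- 250 bp, reversed for '-' strand occurrences so flanks align
biologically) is bias-corrected, averaged over occurrences accessible in
the cell scope, and depth-normalized to insertions-per-million within the
contribution's peaks.  The footprint score is the mean signal over the
50 bp immediately flanking the motif on each side — where a bound TF
leaves elevated signal next to its protected core.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io_formats import CellTypeMap, Fragment, PeakByCellMatrix, PeakRegion
from .motif_scan import MatchMatrix, Motif, MotifOccurrence

logger = logging.getLogger(__name__)

FLANK_BP = 50
WINDOW_BP = 250


# ---------------------------------------------------------------------------
# Insertion index
# ---------------------------------------------------------------------------

@dataclass
class InsertionIndex:
    """Per-chromosome sparse (position x cell) Tn5 insertion counts."""

    cells: list[str]
    matrices: dict[str, sp.csr_matrix]
    n_skipped_fragments: int = 0

    @property
    def total_insertions(self) -> int:
        return int(sum(m.sum() for m in self.matrices.values()))

    def window(self, chrom: str, start: int, end: int) -> sp.csr_matrix:
        """Insertion counts over [start, end), zero-padded outside bounds."""
        n_cells = len(self.cells)
        width = end - start
        mat = self.matrices.get(chrom)
        if mat is None:
            return sp.csr_matrix((width, n_cells))
        lo, hi = max(0, start), min(mat.shape[0], end)
        if hi <= lo:
            return sp.csr_matrix((width, n_cells))
        core = mat[lo:hi]
        if lo == start and hi == end:
            return core
        pad_top = sp.csr_matrix((lo - start, n_cells))
        pad_bot = sp.csr_matrix((end - hi, n_cells))
        return sp.vstack([pad_top, core, pad_bot], format="csr")


def build_insertion_index(fragments: Iterable[Fragment], cells: Sequence[str]) -> InsertionIndex:
    """Index fragment endpoints; fragments shorter than 2 bp are skipped."""
    cell_idx = {bc: i for i, bc in enumerate(cells)}
    per_chrom: dict[str, list] = {}
    skipped = 0
    for f in fragments:
        if f.end - f.start < 2:
            skipped += 1
            continue
        ci = cell_idx.get(f.barcode)
        if ci is None:
            continue
        rows = per_chrom.setdefault(f.chrom, [])
        rows.append((f.start, ci, f.count))
        rows.append((f.end - 1, ci, f.count))
    if skipped:
        logger.info("build_insertion_index: skipped %d sub-2bp fragments", skipped)
    matrices = {}
    for chrom, rows in per_chrom.items():
        pos = np.array([r[0] for r in rows])
        ci = np.array([r[1] for r in rows])
        cnt = np.array([r[2] for r in rows], dtype=float)
        matrices[chrom] = sp.csr_matrix(
            (cnt, (pos, ci)), shape=(int(pos.max()) + 1, len(cells))
        )
    return InsertionIndex(list(cells), matrices, skipped)


# ---------------------------------------------------------------------------
# Tn5 sequence-bias model
# ---------------------------------------------------------------------------

@dataclass
class BiasModel:
    """Centered k-mer observed/expected insertion weights (floor epsilon).

    The k-mer centered on an insertion at ``pos`` spans
    ``[pos - k//2, pos - k//2 + k)``; weight = insertion-site k-mer
    frequency / peak-sequence background frequency.  The uniform model has
    every weight exactly 1.
    """

    k: int = 6
    weights: np.ndarray = field(default_factory=lambda: np.ones(4 ** 6))
    epsilon: float = 1e-3

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("k must be >= 1")
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (4 ** self.k,):
            raise ValueError(f"weights must have length 4^{self.k}")

    @classmethod
    def uniform(cls, k: int = 6) -> "BiasModel":
        return cls(k=k, weights=np.ones(4 ** k))

    def position_weights(self, chrom_seq_codes: np.ndarray) -> np.ndarray:
        """Per-position correction weight along one chromosome; positions
        whose centered k-mer runs off the end or contains N get weight 1."""
        k, half = self.k, self.k // 2
        n = len(chrom_seq_codes)
        w = np.ones(n)
        if n < k:
            return w
        kmers = _kmer_codes(chrom_seq_codes, k)      # index of k-mer starting at i
        valid = kmers >= 0
        centers = np.arange(n - k + 1) + half
        w[centers[valid]] = self.weights[kmers[valid]]
        return w


def _kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Integer code of every k-mer (base-4); -1 where any base is ambiguous."""
    win = np.lib.stride_tricks.sliding_window_view(codes.astype(np.int64), k)
    bad = (win < 0).any(axis=1)
    powers = 4 ** np.arange(k - 1, -1, -1)
    vals = (np.maximum(win, 0) * powers).sum(axis=1)
    vals[bad] = -1
    return vals


def fit_bias_model(genome_codes: Mapping[str, np.ndarray], index: InsertionIndex,
                   peaks: Sequence[PeakRegion], k: int = 6,
                   epsilon: float = 1e-3) -> BiasModel:
    """Fit observed/expected centered k-mer weights from insertions in peaks.

    Falls back to the uniform model (with a warning) below 1000 in-peak
    insertions.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    half = k // 2
    obs = np.zeros(4 ** k)
    bg = np.zeros(4 ** k)
    n_insertions = 0
    for peak in peaks:
        codes = genome_codes[peak.chrom]
        mat = index.matrices.get(peak.chrom)
        # background: every k-mer fully inside the chromosome whose center
        # lies within the peak
        lo = max(0, peak.start - half)
        hi = min(len(codes), peak.end + (k - half))
        seg = codes[lo:hi]
        if len(seg) >= k:
            kmers = _kmer_codes(seg, k)
            centers = np.arange(lo, lo + len(kmers)) + half
            keep = (kmers >= 0) & (centers >= peak.start) & (centers < peak.end)
            np.add.at(bg, kmers[keep], 1)
        if mat is None:
            continue
        s, e = peak.start, min(peak.end, mat.shape[0])
        if e <= s:
            continue
        sub = sp.coo_matrix(mat[s:e])
        pos = sub.row + s
        cnt = sub.data
        starts = pos - half
        ok = (starts >= 0) & (starts + k <= len(codes))
        for p, c in zip(starts[ok], cnt[ok]):
            km = codes[p:p + k]
            if (km < 0).any():
                continue
            code = int((km * (4 ** np.arange(k - 1, -1, -1))).sum())
            obs[code] += c
            n_insertions += c
    if n_insertions < 1000:
        logger.warning("fit_bias_model: only %d in-peak insertions; using uniform model",
                       int(n_insertions))
        return BiasModel.uniform(k)
    obs_freq = obs / obs.sum()
    bg_freq = bg / bg.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        w = obs_freq / bg_freq
    w[~np.isfinite(w)] = 1.0
    return BiasModel(k=k, weights=np.maximum(epsilon, w), epsilon=epsilon)


# ---------------------------------------------------------------------------
# Footprint vectors and scores
# ---------------------------------------------------------------------------

@dataclass
class FootprintVector:
    motif_id: str
    contribution: str
    values: np.ndarray            # length 500 + motif length
    motif_length: int

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != 2 * WINDOW_BP + self.motif_length:
            raise ValueError(
                f"footprint vector length {len(self.values)} != 500 + {self.motif_length}"
            )


def flank_indices(L: int) -> np.ndarray:
    """0-based indices of the 50 bp flanks on each side of the motif."""
    left = np.arange(WINDOW_BP - FLANK_BP, WINDOW_BP)
    right = np.arange(WINDOW_BP + L, WINDOW_BP + L + FLANK_BP)
    return np.concatenate([left, right])


def footprint_score(fp: FootprintVector | np.ndarray, L: Optional[int] = None) -> float:
    """Mean signal over the two 50 bp flanks; NaN inputs give NaN."""
    if isinstance(fp, FootprintVector):
        values, L = fp.values, fp.motif_length
    else:
        values = np.asarray(fp, dtype=float)
        if L is None:
            L = len(values) - 2 * WINDOW_BP
    if len(values) != 2 * WINDOW_BP + L:
        raise ValueError("footprint vector length does not equal 500 + motif length")
    return float(values[flank_indices(L)].mean())


def _corrected_windows(index: InsertionIndex, bias_weights: Optional[Mapping[str, np.ndarray]],
                       peak: PeakRegion, occ: MotifOccurrence, L: int) -> sp.csr_matrix:
    g_start = peak.start + occ.offset - WINDOW_BP
    g_end = peak.start + occ.offset + L + WINDOW_BP
    win = index.window(peak.chrom, g_start, g_end)
    if bias_weights is not None and peak.chrom in bias_weights:
        w = bias_weights[peak.chrom]
        pos = np.arange(g_start, g_end)
        inside = (pos >= 0) & (pos < len(w))
        wvec = np.ones(g_end - g_start)
        wvec[inside] = w[pos[inside]]
        win = sp.diags(1.0 / wvec) @ win
    if occ.strand == "-":
        win = win[::-1]
    return sp.csr_matrix(win)


def footprint_vector(motif: Motif, occurrences: Sequence[MotifOccurrence],
                     index: InsertionIndex, bias_weights: Optional[Mapping[str, np.ndarray]],
                     cell_scope: Sequence[str], D_sub: PeakByCellMatrix,
                     contribution: str = "") -> FootprintVector:
    """Pooled footprint vector over a cell scope (one cell or one type).

    Occurrences are restricted to peaks accessible in the scope (total
    count >= 1); the vector is the occurrence-mean of bias-corrected
    insertion counts, depth-normalized to insertions-per-million within the
    contribution's peaks for the scope.
    """
    L = motif.length
    n = 2 * WINDOW_BP + L
    scope_idx = [D_sub.cells.index(c) for c in cell_scope]
    peak_by_id = {p.id: p for p in D_sub.peaks}
    scope_counts = np.asarray(D_sub.counts[:, scope_idx].sum(axis=1)).ravel()
    accessible = {p.id for p, tot in zip(D_sub.peaks, scope_counts) if tot >= 1}
    kept = [o for o in occurrences
            if o.motif_id == motif.id and o.peak_id in accessible]
    if not kept:
        logger.warning("footprint_vector: motif %s has no accessible occurrence in scope",
                       motif.id)
        return FootprintVector(motif.id, contribution, np.full(n, np.nan), L)

    index_scope = _scope_columns(index, D_sub.cells, scope_idx)
    total = np.zeros(n)
    for o in kept:
        win = _corrected_windows(index_scope, bias_weights, peak_by_id[o.peak_id], o, L)
        total += np.asarray(win.sum(axis=1)).ravel()
    mean_signal = total / len(kept)

    depth = _scope_depth(index, D_sub, scope_idx)
    if depth == 0:
        return FootprintVector(motif.id, contribution, np.full(n, np.nan), L)
    return FootprintVector(motif.id, contribution, mean_signal / (depth / 1e6), L)


def _scope_columns(index: InsertionIndex, cells: Sequence[str],
                   scope_idx: Sequence[int]) -> InsertionIndex:
    mats = {c: m[:, list(scope_idx)] for c, m in index.matrices.items()}
    return InsertionIndex([cells[i] for i in scope_idx], mats)


def _scope_depth(index: InsertionIndex, D_sub: PeakByCellMatrix,
                 scope_idx: Sequence[int]) -> float:
    """Total raw insertions within the contribution's peaks for the scope."""
    depth = 0.0
    for p in D_sub.peaks:
        win = index.window(p.chrom, p.start, p.end)[:, list(scope_idx)]
        depth += win.sum()
    return float(depth)


@dataclass
class FootprintResult:
    """Per-cell and per-cell-type footprint score matrices plus pooled vectors."""

    per_cell: pd.DataFrame                       # motifs x cells, NaN = missing
    per_type: pd.DataFrame                       # motifs x cell types
    pooled_vectors: dict                         # (motif_id, cell_type) -> FootprintVector
    contribution: str


def footprint_matrix(motif_list: Sequence[Motif], D_sub: PeakByCellMatrix,
                     match: MatchMatrix, index: InsertionIndex,
                     bias_weights: Optional[Mapping[str, np.ndarray]],
                     ctmap: CellTypeMap, contribution: str = "") -> FootprintResult:
    """Footprint scores per cell, averaged per cell type, plus pooled
    per-cell-type vectors for signal plots.

    Per-cell scores follow the literal per-cell recipe (scope = one cell,
    missing when the cell has no insertion within the contribution's
    peaks); the per-type matrix is the mean over a type's cells ignoring
    missing entries.
    """
    cells = list(D_sub.cells)
    n_cells = len(cells)
    peak_by_id = {p.id: p for p in D_sub.peaks}
    peak_index = {p.id: i for i, p in enumerate(D_sub.peaks)}
    D = D_sub.counts.tocsr()

    # per-cell depth within contribution peaks
    depth = np.zeros(n_cells)
    for p in D_sub.peaks:
        win = index.window(p.chrom, p.start, p.end)
        depth += np.asarray(win.sum(axis=0)).ravel()

    per_cell = np.full((len(motif_list), n_cells), np.nan)
    occ_by_motif: dict[str, list] = {}
    for o in match.occurrences:
        occ_by_motif.setdefault(o.motif_id, []).append(o)

    # cell-type indicator for pooled (per-type) vectors
    type_labels = sorted({ctmap[bc] for bc in cells if bc in ctmap})
    t_index = {t: j for j, t in enumerate(type_labels)}
    G = np.zeros((n_cells, len(type_labels)))
    for ci, bc in enumerate(cells):
        if bc in ctmap:
            G[ci, t_index[ctmap[bc]]] = 1.0
    depth_ct = depth @ G

    pooled: dict = {}
    for mi, motif in enumerate(motif_list):
        occs = occ_by_motif.get(motif.id, [])
        L = motif.length
        n = 2 * WINDOW_BP + L
        if not occs:
            for ct in type_labels:
                pooled[(motif.id, ct)] = FootprintVector(
                    motif.id, contribution, np.full(n, np.nan), L)
            continue
        fidx = flank_indices(L)
        acc = np.zeros((len(occs), n_cells), dtype=bool)
        flank_sum = np.zeros(n_cells)
        pooled_sum = np.zeros((n, len(type_labels)))
        pooled_nacc = np.zeros(len(type_labels))
        for oi, o in enumerate(occs):
            acc[oi] = np.asarray(D[peak_index[o.peak_id]].todense()).ravel() >= 1
            win = _corrected_windows(index, bias_weights, peak_by_id[o.peak_id], o, L)
            contrib = np.asarray(win[fidx.tolist(), :].sum(axis=0)).ravel()
            flank_sum += np.where(acc[oi], contrib, 0.0)
            acc_ct = (acc[oi] @ G) >= 1            # scope-accessible per type
            win_ct = np.asarray((win @ sp.csr_matrix(G)).todense())
            pooled_sum += win_ct * acc_ct[None, :]
            pooled_nacc += acc_ct
        n_acc = acc.sum(axis=0).astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            score = (flank_sum / n_acc / len(fidx)) / (depth / 1e6)
        score[(n_acc == 0) | (depth == 0)] = np.nan
        per_cell[mi] = score
        with np.errstate(divide="ignore", invalid="ignore"):
            pooled_fp = (pooled_sum / pooled_nacc[None, :]) / (depth_ct[None, :] / 1e6)
        for ct, j in t_index.items():
            vals = pooled_fp[:, j]
            if pooled_nacc[j] == 0 or depth_ct[j] == 0:
                vals = np.full(n, np.nan)
            pooled[(motif.id, ct)] = FootprintVector(motif.id, contribution, vals, L)

    per_cell_df = pd.DataFrame(per_cell, index=[m.id for m in motif_list], columns=cells)
    from .preprocess import aggregate_by_celltype
    per_type_df = aggregate_by_celltype(per_cell_df, ctmap)
    return FootprintResult(per_cell_df, per_type_df, pooled, contribution)


def write_pooled_vectors(pooled: Mapping, path) -> None:
    with open(path, "w") as fh:
        fh.write("motif_id\tcell_type\tposition\tvalue\n")
        for (mid, ct), fp in pooled.items():
            for i, v in enumerate(fp.values, start=1):
                fh.write(f"{mid}\t{ct}\t{i}\t{v:.6g}\n")
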