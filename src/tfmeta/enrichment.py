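"""Per-contribution motif-enrichment deviation z-scores.

For a contribution submatrix ``D`` (peaks x cells) and a motif's binary
match row, the raw deviation of cell ``c`` is ``(X_c - E_c) / E_c`` where
``X_c`` sums counts over matched peaks and ``E_c`` is the expected sum
under the global per-peak accessibility fractions.  The deviation is then
standardized against ``n_background`` sets of GC- and accessibility-matched
background peaks: ``z = (dev - mean_bg) / sd_bg``.  Promoter and enhancer
z-scores come from two independent calls on the respective submatrices.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.neighbors import NearestNeighbors

from .io_formats import PeakByCellMatrix
from .motif_scan import MatchMatrix


@dataclass
class PeakCovariates:
    """Background-matching covariates: GC fraction and mean accessibility."""

    peak_ids: list[str]
    gc_fraction: np.ndarray
    mean_accessibility: np.ndarray

    def __post_init__(self):
        self.gc_fraction = np.asarray(self.gc_fraction, dtype=float)
        self.mean_accessibility = np.asarray(self.mean_accessibility, dtype=float)
        n = len(self.peak_ids)
        if len(self.gc_fraction) != n or len(self.mean_accessibility) != n:
            raise ValueError("covariate arrays do not match peak count")
        if not (np.isfinite(self.gc_fraction).all()
                and np.isfinite(self.mean_accessibility).all()):
            raise ValueError("non-finite covariates")

    def standardized(self) -> np.ndarray:
        X = np.column_stack([self.gc_fraction, np.log1p(self.mean_accessibility)])
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        return (X - X.mean(axis=0)) / sd


def compute_covariates(D_sub: PeakByCellMatrix, genome: Mapping[str, str]) -> PeakCovariates:
    """GC fraction from the genomic sequence, mean count across cells."""
    gc = []
    for p in D_sub.peaks:
        chrom = genome[p.chrom]
        seq = (str(chrom[:]) if not isinstance(chrom, str) else chrom)[p.start:p.end].upper()
        gc.append((seq.count("G") + seq.count("C")) / max(1, len(seq)))
    mean_acc = np.asarray(D_sub.counts.mean(axis=1)).ravel()
    return PeakCovariates(D_sub.peak_ids, np.array(gc), mean_acc)


@dataclass
class EnrichmentMatrix:
    """Motif x cell (or x cell-type) deviation z-scores for one contribution."""

    z: pd.DataFrame                  # motifs x cells, NaN where undefined
    raw: pd.DataFrame                # raw deviations, same shape
    contribution: str                # 'prom' or 'enhD'
    n_background: int
    seed: int


def peak_expectation(D_sub: PeakByCellMatrix) -> np.ndarray:
    """Per-peak fraction of the grand total count; sums to 1."""
    totals = np.asarray(D_sub.counts.sum(axis=1)).ravel().astype(float)
    grand = totals.sum()
    if grand == 0:
        raise ValueError("all-zero count matrix: peak expectation undefined")
    return totals / grand


def raw_deviation(D_sub: PeakByCellMatrix, match_row: np.ndarray,
                  f: Optional[np.ndarray] = None) -> np.ndarray:
    """Raw deviation per cell; NaN where the expected count is zero."""
    if f is None:
        f = peak_expectation(D_sub)
    match_row = np.asarray(match_row, dtype=bool)
    D = np.asarray(D_sub.counts.todense(), dtype=float)
    X = D[match_row, :].sum(axis=0)
    E = f[match_row].sum() * D.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        dev = (X - E) / E
    dev[E == 0] = np.nan
    return dev


def sample_background_sets(covariates: PeakCovariates, match_row: np.ndarray,
                           n_background: int = 50, seed: int = 0,
                           k: Optional[int] = None) -> list[np.ndarray]:
    """Draw ``n_background`` background peak sets matched on (GC, log1p
    mean accessibility): each matched peak is replaced by one of its k
    nearest covariate neighbors (self-sampling allowed), with replacement.
    """
    if n_background < 1:
        raise ValueError("n_background must be >= 1")
    X = covariates.standardized()
    n_peaks = X.shape[0]
    k = min(50, n_peaks) if k is None else min(k, n_peaks)
    neighbor_idx, k = _neighbor_table(X, k)
    matched = np.flatnonzero(np.asarray(match_row, dtype=bool))
    rng = np.random.default_rng(seed)
    sets = []
    for _ in range(n_background):
        choice = rng.integers(0, k, size=len(matched))
        sets.append(neighbor_idx[matched, choice])
    return sets


def _neighbor_table(X: np.ndarray, k: int) -> tuple[np.ndarray, int]:
    """k-nearest-neighbor index table; with all covariates identical the
    neighborhood degenerates to the whole peak set (uniform sampling)."""
    n_peaks = X.shape[0]
    if n_peaks < 2:
        raise ValueError("background sampling needs at least 2 peaks")
    if len(np.unique(X, axis=0)) == 1:
        return np.tile(np.arange(n_peaks), (n_peaks, 1)), n_peaks
    nn = NearestNeighbors(n_neighbors=k).fit(X)
    return nn.kneighbors(X, return_distance=False), k


def _deviation_dense(D: np.ndarray, weight_rows: sp.spmatrix, f: np.ndarray) -> np.ndarray:
    """Deviations for many (possibly multiset) match rows at once."""
    colsums = D.sum(axis=0)
    X = weight_rows @ D
    E = np.outer(weight_rows @ f, colsums)
    with np.errstate(divide="ignore", invalid="ignore"):
        dev = (X - E) / E
    dev[E == 0] = np.nan
    return dev


def enrichment_zscores(D_sub: PeakByCellMatrix, match_matrix: MatchMatrix,
                       covariates: PeakCovariates, n_background: int = 50,
                       seed: int = 0, contribution: str = "",
                       k: Optional[int] = None) -> EnrichmentMatrix:
    """Deviation z-scores for every motif against matched backgrounds."""
    if n_background < 2:
        raise ValueError("n_background must be >= 2 (background sd undefined)")
    if match_matrix.peak_ids != D_sub.peak_ids:
        raise ValueError("match matrix peak axis does not match the contribution submatrix")
    f = peak_expectation(D_sub)
    D = np.asarray(D_sub.counts.todense(), dtype=float)
    M = sp.csr_matrix(match_matrix.matrix, dtype=float)
    M.data[:] = 1.0
    dev = _deviation_dense(D, M, f)

    X = covariates.standardized()
    n_peaks = X.shape[0]
    kk = min(50, n_peaks) if k is None else min(k, n_peaks)
    neighbor_idx, kk = _neighbor_table(X, kk)

    rng = np.random.default_rng(seed)
    n_motifs, n_cells = M.shape[0], D.shape[1]
    bg_devs = np.empty((n_background, n_motifs, n_cells))
    rows_of = [M.indices[M.indptr[m]:M.indptr[m + 1]] for m in range(n_motifs)]
    for b in range(n_background):
        r_idx, c_idx = [], []
        for m, matched in enumerate(rows_of):
            if len(matched) == 0:
                continue
            choice = rng.integers(0, kk, size=len(matched))
            sampled = neighbor_idx[matched, choice]
            r_idx.extend([m] * len(sampled))
            c_idx.extend(sampled.tolist())
        W = sp.csr_matrix(
            (np.ones(len(r_idx)), (r_idx, c_idx)), shape=(n_motifs, n_peaks)
        )
        bg_devs[b] = _deviation_dense(D, W, f)

    import warnings
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # all-NaN background slices (motifs without matches) are handled below
        warnings.simplefilter("ignore", category=RuntimeWarning)
        mu = np.nanmean(bg_devs, axis=0)
        sd = np.nanstd(bg_devs, axis=0, ddof=1)
        z = (dev - mu) / sd
    z[~np.isfinite(z)] = np.nan
    for m, matched in enumerate(rows_of):
        if len(matched) == 0:
            # no matched peak: deviations undefined everywhere
            z[m, :] = np.nan
            dev[m, :] = np.nan
        elif len(matched) == n_peaks:
            # matches every peak: raw deviation is identically 0 and a
            # full-coverage background is equally 0, so z is 0/0 -> missing
            z[m, :] = np.nan

    cells = list(D_sub.cells)
    index = list(match_matrix.motif_ids)
    return EnrichmentMatrix(
        z=pd.DataFrame(z, index=index, columns=cells),
        raw=pd.DataFrame(dev, index=index, columns=cells),
        contribution=contribution,
        n_background=n_background,
        seed=seed,
    )
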