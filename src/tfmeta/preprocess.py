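"""Cell quality control and cell-type (pseudobulk) aggregation.

QC bounds are inclusive: a cell sitting exactly on a threshold is kept
(cells are removed only when *over* the upper or *below* the lower bound).
Aggregation is the unweighted arithmetic mean over the cells of each type,
ignoring missing values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io_formats import CellTypeMap

logger = logging.getLogger(__name__)


@dataclass
class QCConfig:
    """Cell-level QC thresholds (defaults follow standard multiome practice)."""

    max_genes: int = 2500
    min_genes: int = 200
    max_mito_pct: float = 5.0
    max_fragments: int = 30000
    min_fragments: int = 3000
    # no defaults for these two: disabled unless configured
    max_nucleosome_signal: Optional[float] = None
    min_tss_enrichment: Optional[float] = None

    def __post_init__(self):
        if self.max_genes <= self.min_genes:
            raise ValueError("max_genes must exceed min_genes")
        if self.max_fragments <= self.min_fragments:
            raise ValueError("max_fragments must exceed min_fragments")
        if not 0 <= self.max_mito_pct <= 100:
            raise ValueError("max_mito_pct must be in [0, 100]")


@dataclass
class CellMetrics:
    barcode: str
    n_unique_genes: int
    mito_pct: float
    n_fragments: int
    nucleosome_signal: Optional[float] = None
    tss_enrichment: Optional[float] = None

    def __post_init__(self):
        if self.n_unique_genes < 0 or self.n_fragments < 0:
            raise ValueError(f"{self.barcode}: negative QC metric")
        if not 0 <= self.mito_pct <= 100:
            raise ValueError(f"{self.barcode}: mito_pct outside [0, 100]")


def qc_filter_cells(metrics: Sequence[CellMetrics], cfg: QCConfig) -> set[str]:
    """Return the barcodes passing every QC bound (bounds inclusive)."""
    seen = set()
    for m in metrics:
        if m.barcode in seen:
            raise ValueError(f"duplicate barcode in QC metrics: {m.barcode}")
        seen.add(m.barcode)
    retained = set()
    for m in metrics:
        ok = (cfg.min_genes <= m.n_unique_genes <= cfg.max_genes
              and m.mito_pct <= cfg.max_mito_pct
              and cfg.min_fragments <= m.n_fragments <= cfg.max_fragments)
        if ok and cfg.max_nucleosome_signal is not None and m.nucleosome_signal is not None:
            ok = m.nucleosome_signal <= cfg.max_nucleosome_signal
        if ok and cfg.min_tss_enrichment is not None and m.tss_enrichment is not None:
            ok = m.tss_enrichment >= cfg.min_tss_enrichment
        if ok:
            retained.add(m.barcode)
    return retained


def read_metrics_tsv(path) -> list[CellMetrics]:
    df = pd.read_csv(path, sep="\t")
    metrics = []
    for _, row in df.iterrows():
        metrics.append(CellMetrics(
            barcode=str(row["barcode"]),
            n_unique_genes=int(row["n_unique_genes"]),
            mito_pct=float(row["mito_pct"]),
            n_fragments=int(row["n_fragments"]),
            nucleosome_signal=float(row["nucleosome_signal"])
            if "nucleosome_signal" in df.columns else None,
            tss_enrichment=float(row["tss_enrichment"])
            if "tss_enrichment" in df.columns else None,
        ))
    return metrics


def aggregate_by_celltype(
    matrix: Union[pd.DataFrame, np.ndarray, sp.spmatrix],
    ctmap: CellTypeMap,
    cells: Optional[Sequence[str]] = None,
    features: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Average a feature x cell matrix over cell types.

    Returns a feature x cell-type DataFrame with columns in sorted label
    order.  Cells absent from ``ctmap`` are dropped (count logged); missing
    values are ignored in the mean (an all-missing group stays missing).
    A cell type left with zero member cells raises.
    """
    if isinstance(matrix, pd.DataFrame):
        df = matrix
    else:
        if cells is None:
            raise ValueError("cells must be given when matrix has no column labels")
        dense = matrix.toarray() if sp.issparse(matrix) else np.asarray(matrix, dtype=float)
        df = pd.DataFrame(dense, index=list(features) if features is not None else None,
                          columns=list(cells))

    known = [c for c in df.columns if c in ctmap]
    dropped = df.shape[1] - len(known)
    if dropped:
        logger.info("aggregate_by_celltype: dropped %d cells absent from the cell-type map",
                    dropped)
    labels = pd.Series({c: ctmap[c] for c in known})
    present = set(labels.values)
    missing_types = [t for t in ctmap.labels() if t not in present]
    if missing_types:
        raise ValueError(
            "cell types with zero member cells after dropping: " + ", ".join(missing_types)
        )
    sub = df[known]
    agg = sub.T.groupby(labels).mean().T   # pandas mean skips NaN; all-NaN -> NaN
    return agg[sorted(agg.columns)]
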