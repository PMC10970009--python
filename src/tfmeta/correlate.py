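"""Pearson correlation of aggregated TF expression against motif information.

For every mapped motif, the expression of its TF gene across aggregated
cell types is correlated with the motif's information row (enrichment
z-score or footprint score) for each contribution.  With a handful of cell
types n is small, so p-values are low-power; they are two-sided, from the
t transform of r on n - 2 degrees of freedom, with no multiplicity
correction in the headline summary (a Benjamini-Hochberg column is
exported alongside).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

CONTRIBUTIONS = ("prom", "enhD")
INFO_TYPES = ("enrichment", "footprint")


@dataclass
class CorrelationRecord:
    motif_id: str
    gene: str
    contribution: str
    info_type: str
    r: Optional[float]
    p: Optional[float]
    n_ct: int
    reason: str = ""              # empty when r/p are defined

    @property
    def defined(self) -> bool:
        return self.r is not None


def pearson_with_p(x: Sequence[float], y: Sequence[float]) -> tuple:
    """Sample Pearson r with a two-sided p from t = r*sqrt((n-2)/(1-r^2)).

    Pairs where either value is missing are dropped.  Returns
    ``(r, p, n, reason)`` with ``r``/``p`` None (and a reason code) when
    fewer than 3 complete pairs remain or either vector is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        return None, None, n, "n_lt_3"
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None, None, n, "zero_variance"
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0, n, ""
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return r, p, n, ""


def correlate_all(E_agg: pd.DataFrame, info_agg: pd.DataFrame,
                  motif_gene_map: dict, contribution: str,
                  info_type: str) -> list[CorrelationRecord]:
    """One record per mapped motif: expression of its gene vs its info row,
    both across the shared cell-type axis."""
    shared = [ct for ct in info_agg.columns if ct in E_agg.columns]
    if not shared:
        raise ValueError("expression and info matrices share no cell types")
    records = []
    for motif_id, gene in motif_gene_map.items():
        gene = gene.upper()
        if motif_id not in info_agg.index:
            records.append(CorrelationRecord(motif_id, gene, contribution, info_type,
                                             None, None, 0, "motif_missing"))
            continue
        if gene not in E_agg.index:
            records.append(CorrelationRecord(motif_id, gene, contribution, info_type,
                                             None, None, 0, "gene_not_in_expression"))
            continue
        x = E_agg.loc[gene, shared].to_numpy(dtype=float)
        y = info_agg.loc[motif_id, shared].to_numpy(dtype=float)
        r, p, n, reason = pearson_with_p(x, y)
        records.append(CorrelationRecord(motif_id, gene, contribution, info_type,
                                         r, p, n, reason))
    return records


@dataclass
class SummaryTable:
    """Per (contribution, info_type): fraction of TFs passing r and p cuts."""

    table: pd.DataFrame           # columns: contribution, info_type, n_defined,
                                  # n_passing, fraction


def summarize(records: Iterable[CorrelationRecord], r_threshold: float = 0.5,
              p_threshold: float = 0.05) -> SummaryTable:
    """Fraction of records with defined r exceeding ``r_threshold`` at
    ``p < p_threshold`` (raw p, no multiplicity correction)."""
    rows = {}
    for rec in records:
        key = (rec.contribution, rec.info_type)
        n_def, n_pass = rows.get(key, (0, 0))
        if rec.defined:
            n_def += 1
            if rec.r > r_threshold and rec.p < p_threshold:
                n_pass += 1
        rows[key] = (n_def, n_pass)
    out = []
    for (contrib, info), (n_def, n_pass) in sorted(rows.items()):
        frac = n_pass / n_def if n_def else np.nan
        out.append({"contribution": contrib, "info_type": info,
                    "n_defined": n_def, "n_passing": n_pass, "fraction": frac})
    return SummaryTable(pd.DataFrame(out, columns=["contribution", "info_type",
                                                   "n_defined", "n_passing", "fraction"]))


def records_to_frame(records: Iterable[CorrelationRecord]) -> pd.DataFrame:
    df = pd.DataFrame([{
        "motif_id": r.motif_id, "gene": r.gene, "contribution": r.contribution,
        "info_type": r.info_type, "r": r.r, "p": r.p, "n_ct": r.n_ct,
        "reason": r.reason,
    } for r in records])
    if len(df) and df["p"].notna().any():
        df["p_bh"] = _benjamini_hochberg(df["p"].to_numpy(dtype=float))
    else:
        df["p_bh"] = np.nan
    return df


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    adj = np.full_like(p, np.nan, dtype=float)
    ok = np.isfinite(p)
    pv = p[ok]
    m = len(pv)
    if m == 0:
        return adj
    order = np.argsort(pv)
    ranked = pv[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    adj[ok] = out
    return adj


def export_plot_data(records: Iterable[CorrelationRecord], E_agg: pd.DataFrame,
                     enrich_agg: Optional[pd.DataFrame] = None,
                     footprint_agg: Optional[pd.DataFrame] = None) -> dict:
    """Long-format scatter table (cell_type, motif, gene, expression,
    enrichment, footprint_score) plus per-motif across-cell-type
    variability (SD of aggregated enrichment) for variability rankings."""
    seen = {}
    for rec in records:
        seen.setdefault(rec.motif_id, rec.gene)
    rows = []
    ref = enrich_agg if enrich_agg is not None else footprint_agg
    cell_types = list(ref.columns) if ref is not None else list(E_agg.columns)
    for motif_id, gene in seen.items():
        for ct in cell_types:
            expr = float(E_agg.loc[gene, ct]) if gene in E_agg.index else np.nan
            enr = (float(enrich_agg.loc[motif_id, ct])
                   if enrich_agg is not None and motif_id in enrich_agg.index else np.nan)
            fps = (float(footprint_agg.loc[motif_id, ct])
                   if footprint_agg is not None and motif_id in footprint_agg.index else np.nan)
            rows.append({"cell_type": ct, "motif_id": motif_id, "gene": gene,
                         "expression": expr, "enrichment": enr, "footprint_score": fps})
    scatter = pd.DataFrame(rows)
    variability = (enrich_agg.std(axis=1, ddof=1)
                   if enrich_agg is not None else pd.Series(dtype=float))
    variability = variability.rename("enrichment_sd").sort_values(ascending=False)
    return {"scatter": scatter, "variability": variability}
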