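"""Peak labeling by annotation overlap and contribution submatrices.

Peaks are labeled ``prom``, ``enhD`` or ``exon`` when they share at least
``min_overlap_bp`` bases with a promoter, distal-enhancer or exon
annotation region; unlabeled peaks get ``none``.  When a peak overlaps
several annotation classes the priority order (default prom > enhD > exon)
decides — promoter signal dominates TSS-proximal peaks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .io_formats import PeakByCellMatrix, PeakRegion

logger = logging.getLogger(__name__)

LABELS = ("prom", "enhD", "exon", "none")
DEFAULT_PRIORITY = ("prom", "enhD", "exon")


def _max_overlap_bp(peak: PeakRegion, regions_by_chrom: dict) -> int:
    """Total shared bases between a peak and the merged regions of a class."""
    arr = regions_by_chrom.get(peak.chrom)
    if arr is None:
        return 0
    starts, ends = arr
    lo = np.searchsorted(ends, peak.start, side="right")
    hi = np.searchsorted(starts, peak.end, side="left")
    if hi <= lo:
        return 0
    ov = np.minimum(ends[lo:hi], peak.end) - np.maximum(starts[lo:hi], peak.start)
    return int(ov[ov > 0].sum())


def _merge_regions(regions: Sequence[PeakRegion]) -> dict:
    """Merge overlapping regions per chromosome into sorted interval arrays."""
    by_chrom: dict[str, list] = {}
    for r in sorted(regions, key=lambda r: (r.chrom, r.start, r.end)):
        ivals = by_chrom.setdefault(r.chrom, [])
        if ivals and r.start <= ivals[-1][1]:
            ivals[-1][1] = max(ivals[-1][1], r.end)
        else:
            ivals.append([r.start, r.end])
    return {
        c: (np.array([s for s, _ in iv]), np.array([e for _, e in iv]))
        for c, iv in by_chrom.items()
    }


def label_peaks(
    peaks: Sequence[PeakRegion],
    prom_regions: Sequence[PeakRegion],
    enh_regions: Sequence[PeakRegion],
    exon_regions: Sequence[PeakRegion],
    min_overlap_bp: int = 1,
    priority: Sequence[str] = DEFAULT_PRIORITY,
) -> dict[str, str]:
    """Assign each peak one contribution label by annotation overlap."""
    if min_overlap_bp < 1:
        raise ValueError("min_overlap_bp must be >= 1")
    if sorted(priority) != sorted(DEFAULT_PRIORITY):
        raise ValueError(f"priority must be a permutation of {DEFAULT_PRIORITY}")
    merged = {
        "prom": _merge_regions(prom_regions),
        "enhD": _merge_regions(enh_regions),
        "exon": _merge_regions(exon_regions),
    }
    annotated_chroms = set()
    for m in merged.values():
        annotated_chroms.update(m)
    table: dict[str, str] = {}
    warned: set[str] = set()
    for peak in peaks:
        if peak.chrom not in annotated_chroms and peak.chrom not in warned:
            logger.warning("chromosome %s absent from all annotations; peaks labeled none",
                           peak.chrom)
            warned.add(peak.chrom)
        label = "none"
        for cls in priority:
            if _max_overlap_bp(peak, merged[cls]) >= min_overlap_bp:
                label = cls
                break
        table[peak.id] = label
    return table


@dataclass
class ContributionSplit:
    """The peak matrix split into promoter / enhancer / exon submatrices."""

    prom: PeakByCellMatrix
    enhD: PeakByCellMatrix
    exon: PeakByCellMatrix
    label_table: dict[str, str]

    def __getitem__(self, label: str) -> PeakByCellMatrix:
        if label not in ("prom", "enhD", "exon"):
            raise KeyError(label)
        return getattr(self, label)


def split_contributions(D: PeakByCellMatrix, label_table: Mapping[str, str]) -> ContributionSplit:
    """Split D's rows by contribution label, preserving row order and counts."""
    missing = [p.id for p in D.peaks if p.id not in label_table]
    if missing:
        raise ValueError(f"label table does not cover {len(missing)} peaks "
                         f"(first: {missing[0]})")
    subs = {}
    for cls in ("prom", "enhD", "exon"):
        idx = [i for i, p in enumerate(D.peaks) if label_table[p.id] == cls]
        subs[cls] = D.subset_rows(idx)
    return ContributionSplit(subs["prom"], subs["enhD"], subs["exon"], dict(label_table))


def write_label_table(table: Mapping[str, str], path) -> None:
    with open(path, "w") as fh:
        fh.write("peak_id\tlabel\n")
        for pid in table:
            fh.write(f"{pid}\t{table[pid]}\n")


def read_label_table(path) -> dict[str, str]:
    table = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or (lineno == 1 and line.startswith("peak_id")):
                continue
            pid, label = line.rstrip("\n").split("\t")[:2]
            table[pid] = label
    return table
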