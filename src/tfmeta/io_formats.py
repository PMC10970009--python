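"""Readers and writers for the standard formats the pipeline touches.

All genomic intervals use the BED convention throughout the package:
0-based, half-open ``[start, end)``, so a region of length ``L`` satisfies
``end - start == L``.  MatrixMarket files are 1-based on disk and converted
to 0-based in memory.  Fragment files follow the 10x ``fragments.tsv``
dialect (5 columns, coordinates already Tn5-shifted by the upstream
pipeline; no further +4/-5 shift is applied here).
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
import scipy.io
import scipy.sparse as sp
from Bio import motifs as bio_motifs


class FormatError(ValueError):
    """Raised when an input file violates its declared dialect."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PeakRegion:
    """A genomic interval (0-based, half-open)."""

    chrom: str
    start: int
    end: int
    id: str = ""

    def __post_init__(self):
        if self.start < 0:
            raise FormatError(f"negative start in region {self.chrom}:{self.start}-{self.end}")
        if self.end <= self.start:
            raise FormatError(f"end <= start in region {self.chrom}:{self.start}-{self.end}")
        if not self.id:
            object.__setattr__(self, "id", f"{self.chrom}:{self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class PeakByCellMatrix:
    """Sparse nonnegative peak x cell count matrix with its axis labels."""

    peaks: list[PeakRegion]
    cells: list[str]
    counts: sp.csr_matrix

    def __post_init__(self):
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape != (len(self.peaks), len(self.cells)):
            raise FormatError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.peaks)} peaks x {len(self.cells)} cells"
            )
        if self.counts.nnz and self.counts.data.min() < 0:
            raise FormatError("negative entries in count matrix")
        ids = [p.id for p in self.peaks]
        if len(set(ids)) != len(ids):
            raise FormatError("duplicate peak ids")

    @property
    def peak_ids(self) -> list[str]:
        return [p.id for p in self.peaks]

    def subset_rows(self, idx: Sequence[int]) -> "PeakByCellMatrix":
        idx = list(idx)
        return PeakByCellMatrix(
            [self.peaks[i] for i in idx], list(self.cells), self.counts[idx, :]
        )


@dataclass
class ExpressionMatrix:
    """Gene x cell expression values (raw counts or normalized)."""

    genes: list[str]
    cells: list[str]
    values: np.ndarray
    normalized: bool = False

    def __post_init__(self):
        self.genes = [g.upper() for g in self.genes]
        if len(set(self.genes)) != len(self.genes):
            raise FormatError("gene symbols not unique after uppercasing")
        self.values = np.asarray(
            self.values.todense() if sp.issparse(self.values) else self.values, dtype=float
        )
        if self.values.shape != (len(self.genes), len(self.cells)):
            raise FormatError("expression matrix shape mismatch")
        if np.nanmin(self.values, initial=0.0) < 0:
            raise FormatError("negative expression values")

    def expressed_genes(self) -> set[str]:
        """Genes with nonzero total signal across cells."""
        totals = np.nansum(self.values, axis=1)
        return {g for g, t in zip(self.genes, totals) if t > 0}


@dataclass(frozen=True)
class Fragment:
    chrom: str
    start: int
    end: int
    barcode: str
    count: int = 1

    def __post_init__(self):
        if self.end <= self.start:
            raise FormatError(f"fragment end <= start: {self.chrom}:{self.start}-{self.end}")
        if self.count < 1:
            raise FormatError("fragment count < 1")


@dataclass
class Motif:
    """A TF binding motif as a 4 x L position frequency matrix (rows A,C,G,T)."""

    id: str
    name: str
    pfm: np.ndarray
    gene: Optional[str] = None

    def __post_init__(self):
        self.pfm = np.asarray(self.pfm, dtype=float)
        if self.pfm.ndim != 2 or self.pfm.shape[0] != 4 or self.pfm.shape[1] < 1:
            raise FormatError(f"motif {self.id}: PFM must be 4 x L with L >= 1")
        if self.pfm.min() < 0:
            raise FormatError(f"motif {self.id}: negative PFM entries")
        if (self.pfm.sum(axis=0) <= 0).any():
            raise FormatError(f"motif {self.id}: zero-sum PFM column")

    @property
    def length(self) -> int:
        return self.pfm.shape[1]

    @property
    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.pfm.argmax(axis=0))


@dataclass
class CellTypeMap:
    """barcode -> cell-type label."""

    mapping: dict[str, str]

    def __post_init__(self):
        for bc, label in self.mapping.items():
            if not label:
                raise FormatError(f"empty cell-type label for barcode {bc}")

    def labels(self) -> list[str]:
        return sorted(set(self.mapping.values()))

    def __getitem__(self, barcode: str) -> str:
        return self.mapping[barcode]

    def __contains__(self, barcode: str) -> bool:
        return barcode in self.mapping


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def _parse_bed_line(line: str, lineno: int, path) -> PeakRegion:
    parts = line.rstrip("\n").split("\t")
    if len(parts) < 3:
        raise FormatError(f"{path}:{lineno}: BED line has fewer than 3 columns")
    chrom = parts[0]
    try:
        start, end = int(parts[1]), int(parts[2])
    except ValueError as exc:
        raise FormatError(f"{path}:{lineno}: non-integer BED coordinates") from exc
    name = parts[3] if len(parts) >= 4 and parts[3] not in (".", "") else ""
    try:
        return PeakRegion(chrom, start, end, name)
    except FormatError as exc:
        raise FormatError(f"{path}:{lineno}: {exc}") from exc


def read_bed(path) -> list[PeakRegion]:
    """Read a BED3+ file in input order."""
    regions = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            regions.append(_parse_bed_line(line, lineno, path))
    return regions


def read_annotations(bed_path) -> list[PeakRegion]:
    """Read annotation regions (BED3+), sorted by (chrom, start).

    Overlapping annotation regions are permitted; an empty file yields an
    empty list (downstream labeling then assigns no labels of that class).
    """
    return sorted(read_bed(bed_path), key=lambda r: (r.chrom, r.start, r.end))


def write_bed(regions: Iterable[PeakRegion], path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.id}\n")


# ---------------------------------------------------------------------------
# Peak-by-cell / gene-by-cell matrices (MatrixMarket + sidecar TSVs)
# ---------------------------------------------------------------------------

def _read_lines(path) -> list[str]:
    with open(path) as fh:
        return [ln.rstrip("\n") for ln in fh if ln.strip()]


def read_peak_matrix(mtx_path, peaks_bed_path, barcodes_path) -> PeakByCellMatrix:
    """Read an MTX + peaks BED + barcodes TSV triplet.

    Peaks keep BED order and cells keep barcode-file order; counts are
    preserved exactly.
    """
    counts = sp.csr_matrix(scipy.io.mmread(str(mtx_path)))
    peaks = read_bed(peaks_bed_path)
    cells = _read_lines(barcodes_path)
    if counts.shape[0] != len(peaks):
        raise FormatError(
            f"{mtx_path}: {counts.shape[0]} rows but {peaks_bed_path} has {len(peaks)} peaks"
        )
    if counts.shape[1] != len(cells):
        raise FormatError(
            f"{mtx_path}: {counts.shape[1]} columns but {barcodes_path} has {len(cells)} barcodes"
        )
    return PeakByCellMatrix(peaks, cells, counts)


def write_peak_matrix(pbm: PeakByCellMatrix, mtx_path, peaks_bed_path, barcodes_path) -> None:
    scipy.io.mmwrite(str(mtx_path), sp.coo_matrix(pbm.counts))
    write_bed(pbm.peaks, peaks_bed_path)
    with open(barcodes_path, "w") as fh:
        fh.write("".join(bc + "\n" for bc in pbm.cells))


def read_expression_matrix(mtx_path, features_path, barcodes_path,
                           normalized: bool = False) -> ExpressionMatrix:
    values = sp.csr_matrix(scipy.io.mmread(str(mtx_path)))
    genes = [ln.split("\t")[0] for ln in _read_lines(features_path)]
    cells = _read_lines(barcodes_path)
    if values.shape != (len(genes), len(cells)):
        raise FormatError(
            f"{mtx_path}: shape {values.shape} does not match "
            f"{len(genes)} features x {len(cells)} barcodes"
        )
    return ExpressionMatrix(genes, cells, values, normalized=normalized)


def write_expression_matrix(em: ExpressionMatrix, mtx_path, features_path, barcodes_path) -> None:
    scipy.io.mmwrite(str(mtx_path), sp.coo_matrix(em.values))
    with open(features_path, "w") as fh:
        fh.write("".join(g + "\n" for g in em.genes))
    with open(barcodes_path, "w") as fh:
        fh.write("".join(bc + "\n" for bc in em.cells))


# ---------------------------------------------------------------------------
# Fragments (10x fragments.tsv dialect, gzip-transparent)
# ---------------------------------------------------------------------------

def _open_maybe_gzip(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def read_fragments(path, barcode_whitelist: Optional[set[str]] = None) -> Iterator[Fragment]:
    """Stream fragments from a (possibly gzipped) 4/5-column TSV.

    Rows whose barcode is not in ``barcode_whitelist`` are dropped (all rows
    kept when the whitelist is None); 4-column rows get ``count=1``.
    """
    with _open_maybe_gzip(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 4:
                raise FormatError(f"{path}:{lineno}: fragment line has fewer than 4 columns")
            chrom, barcode = parts[0], parts[3]
            try:
                start, end = int(parts[1]), int(parts[2])
                count = int(parts[4]) if len(parts) >= 5 else 1
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer field") from exc
            if barcode_whitelist is not None and barcode not in barcode_whitelist:
                continue
            try:
                yield Fragment(chrom, start, end, barcode, count)
            except FormatError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc


def write_fragments(fragments: Iterable[Fragment], path) -> None:
    opener = gzip.open(str(path), "wt") if str(path).endswith(".gz") else open(path, "w")
    with opener as fh:
        for f in fragments:
            fh.write(f"{f.chrom}\t{f.start}\t{f.end}\t{f.barcode}\t{f.count}\n")


# ---------------------------------------------------------------------------
# JASPAR PFMs
# ---------------------------------------------------------------------------

def _split_jaspar_records(text: str) -> list[str]:
    records, current = [], []
    for line in text.splitlines():
        if line.startswith(">"):
            if current:
                records.append("\n".join(current))
            current = [line]
        elif line.strip():
            current.append(line)
    if current:
        records.append("\n".join(current))
    return records


def read_jaspar_pfms(path) -> list[Motif]:
    """Read a JASPAR-format (2016+) text file of PFMs, order preserved."""
    with open(path) as fh:
        text = fh.read()
    result = []
    for record in _split_jaspar_records(text):
        header = record.splitlines()[0][1:].strip()
        fields = header.split(None, 1)
        motif_id = fields[0]
        name = fields[1].strip() if len(fields) > 1 else motif_id
        try:
            m = bio_motifs.read(io.StringIO(record), "jaspar")
        except Exception as exc:
            raise FormatError(f"malformed JASPAR record for motif {motif_id}: {exc}") from exc
        pfm = np.array([m.counts[b] for b in "ACGT"], dtype=float)
        result.append(Motif(id=motif_id, name=name, pfm=pfm))
    return result


def write_jaspar_pfms(motif_list: Iterable[Motif], path) -> None:
    with open(path, "w") as fh:
        for m in motif_list:
            fh.write(f">{m.id}\t{m.name}\n")
            for base, row in zip("ACGT", m.pfm):
                vals = " ".join(f"{v:6g}" for v in row)
                fh.write(f"{base}  [ {vals} ]\n")


# ---------------------------------------------------------------------------
# Cell-type map and generic TSV helpers
# ---------------------------------------------------------------------------

def read_cell_type_map(path, known_barcodes: Optional[set[str]] = None) -> CellTypeMap:
    """Read a TSV with columns (barcode, cell_type); a header row is allowed."""
    mapping = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns (barcode, cell_type)")
            if lineno == 1 and parts[0].lower() in ("barcode", "cell"):
                continue
            mapping[parts[0]] = parts[1]
    if known_barcodes is not None:
        unknown = set(mapping) - known_barcodes
        if unknown:
            raise FormatError(f"{path}: {len(unknown)} barcodes not in the dataset")
    return CellTypeMap(mapping)


def write_cell_type_map(ctmap: CellTypeMap, path) -> None:
    with open(path, "w") as fh:
        fh.write("barcode\tcell_type\n")
        for bc in sorted(ctmap.mapping):
            fh.write(f"{bc}\t{ctmap.mapping[bc]}\n")
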