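"""PFM -> log-odds scanning and the motif x peak match matrix.

Scanning uses a relative-score threshold: a window is a match when its
log-odds score is at least ``min_score + rel_threshold * (max_score -
min_score)``.  Both strands are scanned (the reverse strand scores the
reverse complement); windows containing ``N`` are skipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import scipy.sparse as sp

from .io_formats import FormatError, Motif, PeakRegion

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def encode_sequence(seq: str) -> np.ndarray:
    """Map A,C,G,T to 0..3 and any other symbol (N, ...) to -1."""
    table = np.full(256, -1, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        table[ord(base)] = idx
        table[ord(base.lower())] = idx
    return table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def reverse_complement(seq: str) -> str:
    comp = str.maketrans("ACGTNacgtn", "TGCANtgcan")
    return seq.translate(comp)[::-1]


@dataclass
class PWM:
    """Log-odds position weight matrix derived from a PFM."""

    motif_id: str
    matrix: np.ndarray            # 4 x L log2 odds
    background: np.ndarray        # base frequencies, sum 1
    length: int = field(init=False)
    max_score: float = field(init=False)
    min_score: float = field(init=False)

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.length = self.matrix.shape[1]
        self.max_score = float(self.matrix.max(axis=0).sum())
        self.min_score = float(self.matrix.min(axis=0).sum())

    def threshold(self, rel_threshold: float) -> float:
        return self.min_score + rel_threshold * (self.max_score - self.min_score)


@dataclass(frozen=True)
class MotifOccurrence:
    motif_id: str
    peak_id: str
    offset: int                   # 0-based within the peak
    strand: str                   # '+' or '-'
    score: float


def pfm_to_pwm(motif: Motif, background: Optional[Sequence[float]] = None,
               pseudocount: float = 0.8) -> PWM:
    """Convert a PFM to a log2-odds PWM.

    Column ``j``, base ``b`` scores
    ``log2(((pfm[b,j] + pc*bg[b]) / (colsum_j + pc)) / bg[b])`` — the
    pseudocount is distributed according to the background.
    """
    bg = np.asarray(background if background is not None else [0.25] * 4, dtype=float)
    if not np.isclose(bg.sum(), 1.0):
        raise ValueError("background frequencies must sum to 1")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    pfm = motif.pfm
    colsums = pfm.sum(axis=0)
    if (colsums <= 0).any():
        raise FormatError(f"motif {motif.id}: zero-sum PFM column")
    probs = (pfm + pseudocount * bg[:, None]) / (colsums + pseudocount)
    return PWM(motif.id, np.log2(probs / bg[:, None]), bg)


def _invalid_windows(codes: np.ndarray, L: int) -> np.ndarray:
    """Boolean mask of windows containing an ambiguous base."""
    bad = (codes < 0).astype(np.int32)
    cum = np.concatenate([[0], np.cumsum(bad)])
    return (cum[L:] - cum[:-L]) > 0


def _window_scores(codes: np.ndarray, matrix: np.ndarray) -> np.ndarray:
    """Score every window of width L; windows containing N score -inf."""
    L = matrix.shape[1]
    n_win = len(codes) - L + 1
    if n_win <= 0:
        return np.empty(0)
    safe = np.where(codes < 0, 0, codes).astype(np.intp)
    scores = np.zeros(n_win)
    for j in range(L):
        scores += matrix[safe[j:j + n_win], j]
    scores[_invalid_windows(codes, L)] = -np.inf
    return scores


def scan_sequence(pwm: PWM, seq: str, rel_threshold: float = 0.8,
                  peak_id: str = "") -> list[MotifOccurrence]:
    """Report every offset on either strand scoring at or above the
    relative threshold.  The reverse strand scores the reverse complement
    of each window, reported at the same forward-strand offset."""
    if not 0 < rel_threshold <= 1:
        raise ValueError("rel_threshold must be in (0, 1]")
    L = pwm.length
    if len(seq) < L:
        return []
    codes = encode_sequence(seq)
    thr = pwm.threshold(rel_threshold)
    # reverse-complement the PWM instead of the sequence: same scores,
    # offsets stay in forward coordinates
    rc_matrix = pwm.matrix[::-1, ::-1]
    occurrences = []
    for strand, matrix in (("+", pwm.matrix), ("-", rc_matrix)):
        scores = _window_scores(codes, matrix)
        for off in np.flatnonzero(scores >= thr):
            occurrences.append(
                MotifOccurrence(pwm.motif_id, peak_id, int(off), strand, float(scores[off]))
            )
    occurrences.sort(key=lambda o: (o.offset, o.strand))
    return occurrences


@dataclass
class MatchMatrix:
    """Binary motif x peak match matrix plus the underlying occurrences."""

    motif_ids: list[str]
    peak_ids: list[str]
    matrix: sp.csr_matrix         # 1 iff >= 1 occurrence
    occurrences: list[MotifOccurrence]

    def row(self, motif_id: str) -> np.ndarray:
        i = self.motif_ids.index(motif_id)
        return np.asarray(self.matrix[i, :].todense()).ravel().astype(bool)

    def occurrences_for(self, motif_id: str) -> list[MotifOccurrence]:
        return [o for o in self.occurrences if o.motif_id == motif_id]


def _chromosome_sequence(genome, chrom: str) -> str:
    seq = genome[chrom]
    if not isinstance(seq, str):      # pyfaidx.FastaRecord or Bio Seq
        seq = str(seq[:]) if hasattr(seq, "__getitem__") else str(seq)
    return seq


def scan_genome(pwm_list: Sequence[PWM], genome_codes: Mapping[str, np.ndarray],
                rel_threshold: float = 0.8,
                motif_block: int = 32) -> list[list[tuple]]:
    """Batched scan of whole chromosomes with many PWMs at once.

    Returns, per PWM, a list of ``(chrom, position, strand, score)`` hits at
    or above the relative threshold.  Scoring is a single matrix product of
    the flattened PWMs against stacked shifted base indicators, so the whole
    motif set is scanned at BLAS speed.
    """
    hits: list[list[tuple]] = [[] for _ in pwm_list]
    by_length: dict[int, list[int]] = {}
    for i, pwm in enumerate(pwm_list):
        by_length.setdefault(pwm.length, []).append(i)
    for chrom, codes in genome_codes.items():
        N = len(codes)
        onehot = np.zeros((4, N))
        for b in range(4):
            onehot[b, codes == b] = 1.0
        for L, members in by_length.items():
            n_win = N - L + 1
            if n_win <= 0:
                continue
            invalid = _invalid_windows(codes, L)
            # row 4j + b of the design holds indicator of base b at offset j
            design = np.empty((4 * L, n_win))
            for j in range(L):
                design[4 * j:4 * j + 4] = onehot[:, j:j + n_win]
            for b0 in range(0, len(members), motif_block):
                block = members[b0:b0 + motif_block]
                for strand in ("+", "-"):
                    mats = np.stack([
                        pwm_list[i].matrix if strand == "+"
                        else pwm_list[i].matrix[::-1, ::-1]
                        for i in block
                    ])                                     # (G, 4, L)
                    flat = mats.transpose(0, 2, 1).reshape(len(block), 4 * L)
                    scores = flat @ design
                    scores[:, invalid] = -np.inf
                    for g, i in enumerate(block):
                        thr = pwm_list[i].threshold(rel_threshold)
                        for pos in np.flatnonzero(scores[g] >= thr):
                            hits[i].append((chrom, int(pos), strand,
                                            float(scores[g, pos])))
    return hits


def build_match_matrix(motif_list: Sequence[Motif], peaks: Sequence[PeakRegion],
                       genome: Mapping[str, str], rel_threshold: float = 0.8,
                       background: Optional[Sequence[float]] = None,
                       pseudocount: float = 0.8) -> MatchMatrix:
    """Scan every peak with every motif.

    ``genome`` maps chromosome name to sequence (a plain dict of strings or
    a pyfaidx ``Fasta``).  Chromosomes are scanned once per motif batch and
    hits are assigned to the peaks that fully contain them; occurrence
    genomic position = peak start + offset.
    """
    chrom_cache: dict[str, np.ndarray] = {}
    for p in peaks:
        if p.chrom not in chrom_cache:
            try:
                seq = _chromosome_sequence(genome, p.chrom)
            except KeyError as exc:
                raise FormatError(f"peak {p.id}: chromosome {p.chrom} absent from genome") from exc
            chrom_cache[p.chrom] = encode_sequence(seq)
        if p.end > len(chrom_cache[p.chrom]):
            raise FormatError(
                f"peak {p.id} extends beyond chromosome {p.chrom} "
                f"({len(chrom_cache[p.chrom])} bp)"
            )

    # peaks sorted per chromosome for containment lookup
    peaks_by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    max_peak_len = max((len(p) for p in peaks), default=0)
    for pi, p in enumerate(peaks):
        peaks_by_chrom.setdefault(p.chrom, []).append((p.start, p.end, pi))
    for lst in peaks_by_chrom.values():
        lst.sort()

    pwms = [pfm_to_pwm(m, background=background, pseudocount=pseudocount)
            for m in motif_list]
    all_hits = scan_genome(pwms, chrom_cache, rel_threshold)

    starts_by_chrom = {c: np.array([s for s, _, _ in lst])
                       for c, lst in peaks_by_chrom.items()}
    rows, cols = [], []
    seen_pairs = set()
    occurrences = []
    for mi, motif_hits in enumerate(all_hits):
        L = pwms[mi].length
        for chrom, pos, strand, score in motif_hits:
            lst = peaks_by_chrom.get(chrom, [])
            if not lst:
                continue
            k = int(np.searchsorted(starts_by_chrom[chrom], pos, side="right")) - 1
            # walk left while peaks could still contain [pos, pos + L)
            while k >= 0:
                s, e, pi = lst[k]
                if s + max_peak_len < pos:
                    break
                if s <= pos and pos + L <= e:
                    occurrences.append(MotifOccurrence(
                        motif_list[mi].id, peaks[pi].id, pos - s, strand, score))
                    if (mi, pi) not in seen_pairs:
                        seen_pairs.add((mi, pi))
                        rows.append(mi)
                        cols.append(pi)
                k -= 1
    occurrences.sort(key=lambda o: (o.motif_id, o.peak_id, o.offset, o.strand))
    matrix = sp.csr_matrix(
        (np.ones(len(rows), dtype=np.int8), (rows, cols)),
        shape=(len(motif_list), len(peaks)),
    )
    return MatchMatrix([m.id for m in motif_list], [p.id for p in peaks], matrix, occurrences)


def map_motifs_to_genes(motif_list: Iterable[Motif], expressed_genes: Iterable[str],
                        dimer_policy: str = "drop") -> list[Motif]:
    """Keep motifs whose TF name maps (case-insensitively) to an expressed gene.

    Dimer names containing ``::`` are dropped under the default policy;
    ``dimer_policy="require_all"`` keeps a dimer when every subunit gene is
    expressed (the gene field is then the first subunit).
    """
    if dimer_policy not in ("drop", "require_all"):
        raise ValueError(f"unknown dimer_policy {dimer_policy!r}")
    expressed = {g.upper() for g in expressed_genes}
    kept = []
    for m in motif_list:
        if "::" in m.name:
            if dimer_policy == "drop":
                continue
            parts = [p.strip().upper() for p in m.name.split("::")]
            if all(p in expressed for p in parts):
                kept.append(Motif(m.id, m.name, m.pfm.copy(), gene=parts[0]))
            continue
        symbol = m.name.strip().upper()
        if symbol in expressed:
            kept.append(Motif(m.id, m.name, m.pfm.copy(), gene=symbol))
    return kept


# ---------------------------------------------------------------------------
# Persistence: occurrences as BED6, match matrix as MTX + index TSVs
# ---------------------------------------------------------------------------

def write_occurrences_bed(occurrences: Iterable[MotifOccurrence],
                          peaks: Sequence[PeakRegion], motif_lengths: Mapping[str, int],
                          path) -> None:
    by_id = {p.id: p for p in peaks}
    with open(path, "w") as fh:
        for o in occurrences:
            p = by_id[o.peak_id]
            start = p.start + o.offset
            L = motif_lengths[o.motif_id]
            fh.write(f"{p.chrom}\t{start}\t{start + L}\t{o.motif_id};{o.peak_id}"
                     f"\t{o.score:.4f}\t{o.strand}\n")


def write_match_matrix(mm: MatchMatrix, mtx_path, motifs_tsv, peaks_tsv) -> None:
    import scipy.io
    scipy.io.mmwrite(str(mtx_path), sp.coo_matrix(mm.matrix))
    with open(motifs_tsv, "w") as fh:
        fh.write("".join(m + "\n" for m in mm.motif_ids))
    with open(peaks_tsv, "w") as fh:
        fh.write("".join(p + "\n" for p in mm.peak_ids))


def read_occurrences_bed(path, peaks: Sequence[PeakRegion]) -> list[MotifOccurrence]:
    by_id = {p.id: p for p in peaks}
    occurrences = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, start, _end, name, score, strand = line.rstrip("\n").split("\t")[:6]
            motif_id, peak_id = name.split(";", 1)
            p = by_id[peak_id]
            occurrences.append(
                MotifOccurrence(motif_id, peak_id, int(start) - p.start, strand, float(score))
            )
    return occurrences
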