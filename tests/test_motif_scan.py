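import itertools

import numpy as np
import pytest

from tfmeta import Motif, build_match_matrix, map_motifs_to_genes, pfm_to_pwm, scan_sequence
from tfmeta.motif_scan import reverse_complement

BASES = "ACGT"


def _motif_from_consensus(consensus, mid="M1", name="TF1", major=10.0, minor=0.0):
    pfm = np.full((4, len(consensus)), minor)
    for j, b in enumerate(consensus):
        pfm[BASES.index(b), j] = major
    return Motif(mid, name, pfm)


def _brute_scan(pwm, seq, rel_threshold):
    """Independent position-by-position rescan on both strands."""
    thr = pwm.min_score + rel_threshold * (pwm.max_score - pwm.min_score)
    found = []
    for strand, s in (("+", seq), ("-", None)):
        for off in range(len(seq) - pwm.length + 1):
            window = seq[off:off + pwm.length]
            if strand == "-":
                window = reverse_complement(window)
            if any(b not in BASES for b in window):
                continue
            score = sum(pwm.matrix[BASES.index(b), j] for j, b in enumerate(window))
            if score >= thr:
                found.append((off, strand, score))
    return found


class TestPWM:
    def test_log_odds_hand_value(self):
        motif = _motif_from_consensus("A")
        pwm = pfm_to_pwm(motif, pseudocount=0.8)
        # A column 10/0/0/0, uniform bg: log2((10.2/10.8)/0.25)
        assert pwm.matrix[0, 0] == pytest.approx(np.log2((10.2 / 10.8) / 0.25))
        assert pwm.matrix[0, 0] == pytest.approx(1.918, abs=1e-3)

    def test_uniform_column_scores_zero(self):
        motif = Motif("M", "T", np.full((4, 2), 5.0))
        pwm = pfm_to_pwm(motif, pseudocount=0.8)
        np.testing.assert_allclose(pwm.matrix, 0.0, atol=1e-12)

    @pytest.mark.parametrize("L", [2, 4, 6])
    def test_score_bounds_match_exhaustive_enumeration(self, L):
        rng = np.random.default_rng(L)
        motif = Motif("M", "T", rng.integers(1, 20, size=(4, L)).astype(float))
        pwm = pfm_to_pwm(motif)
        scores = [
            sum(pwm.matrix[b, j] for j, b in enumerate(word))
            for word in itertools.product(range(4), repeat=L)
        ]
        assert pwm.max_score == pytest.approx(max(scores))
        assert pwm.min_score == pytest.approx(min(scores))


class TestScanSequence:
    def test_consensus_hits_at_offset_with_max_score(self):
        motif = _motif_from_consensus("ACGTAC")
        pwm = pfm_to_pwm(motif)
        seq = "T" * 7 + "ACGTAC" + "T" * 5
        occs = [o for o in scan_sequence(pwm, seq, 0.99) if o.strand == "+"]
        assert [o.offset for o in occs] == [7]
        assert occs[0].score == pytest.approx(pwm.max_score)

    def test_reverse_complement_reported_on_minus_strand(self):
        motif = _motif_from_consensus("AACCGT")
        pwm = pfm_to_pwm(motif)
        seq = "T" * 4 + reverse_complement("AACCGT") + "T" * 4
        occs = [o for o in scan_sequence(pwm, seq, 0.99) if o.strand == "-"]
        assert [o.offset for o in occs] == [4]

    def test_short_sequence_and_n_windows(self):
        pwm = pfm_to_pwm(_motif_from_consensus("ACGTACGT"))
        assert scan_sequence(pwm, "ACG") == []
        assert scan_sequence(pwm, "ACGTNCGT", 0.1) == []

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_rescan(self, seed):
        rng = np.random.default_rng(seed)
        motif = Motif("M", "T", rng.integers(0, 20, size=(4, 7)).astype(float) + 1)
        pwm = pfm_to_pwm(motif)
        seq = "".join(rng.choice(list(BASES), 200))
        got = [(o.offset, o.strand) for o in scan_sequence(pwm, seq, 0.7)]
        expected = [(off, st) for off, st, _ in _brute_scan(pwm, seq, 0.7)]
        assert sorted(got) == sorted(expected)
        for o in scan_sequence(pwm, seq, 0.7):
            assert pwm.min_score <= o.score <= pwm.max_score

    def test_strand_symmetry(self):
        rng = np.random.default_rng(5)
        motif = Motif("M", "T", rng.integers(1, 15, size=(4, 6)).astype(float))
        pwm = pfm_to_pwm(motif)
        seq = "".join(rng.choice(list(BASES), 120))
        fwd = scan_sequence(pwm, seq, 0.75)
        rc = scan_sequence(pwm, reverse_complement(seq), 0.75)
        flipped = sorted((len(seq) - o.offset - pwm.length, {"+": "-", "-": "+"}[o.strand],
                          round(o.score, 9)) for o in rc)
        assert flipped == sorted((o.offset, o.strand, round(o.score, 9)) for o in fwd)


class TestMatchMatrix:
    def _world(self):
        from tfmeta import PeakRegion
        genome = {"chr1": "T" * 100 + "ACGTACAATCGA" + "T" * 88 + "G" * 200}
        peaks = [PeakRegion("chr1", 50, 250, "pA"), PeakRegion("chr1", 250, 400, "pB")]
        motif = _motif_from_consensus("ACGTACAATCGA", major=20.0, minor=1.0)
        return genome, peaks, motif

    def test_planted_peak_matched_and_position_is_genomic(self):
        genome, peaks, motif = self._world()
        mm = build_match_matrix([motif], peaks, genome, rel_threshold=0.9)
        assert mm.matrix.toarray().tolist() == [[1, 0]]
        occ = mm.occurrences_for("M1")[0]
        assert peaks[0].start + occ.offset == 100

    def test_empty_motif_list(self):
        genome, peaks, _ = self._world()
        mm = build_match_matrix([], peaks, genome)
        assert mm.matrix.shape == (0, 2)

    def test_reversed_peak_order_gives_same_matches(self):
        genome, peaks, motif = self._world()
        fwd = build_match_matrix([motif], peaks, genome, rel_threshold=0.9)
        rev = build_match_matrix([motif], peaks[::-1], genome, rel_threshold=0.9)
        fwd_set = {(o.motif_id, o.peak_id, o.offset, o.strand) for o in fwd.occurrences}
        rev_set = {(o.motif_id, o.peak_id, o.offset, o.strand) for o in rev.occurrences}
        assert fwd_set == rev_set

    def test_peak_beyond_chromosome_end_raises(self):
        from tfmeta import PeakRegion
        from tfmeta.io_formats import FormatError
        genome = {"chr1": "ACGT" * 25}
        with pytest.raises(FormatError, match="pX"):
            build_match_matrix([], [PeakRegion("chr1", 50, 150, "pX")], genome)

    def test_agrees_with_per_peak_scan(self, tiny_dataset, tiny_genome):
        """Whole-genome batched scanning equals scanning each peak alone."""
        from tfmeta import read_jaspar_pfms, read_peak_matrix
        _, _, out = tiny_dataset
        motifs = read_jaspar_pfms(out / "motifs.jaspar")[:5]
        pbm = read_peak_matrix(out / "atac_matrix.mtx", out / "peaks.bed",
                               out / "atac_barcodes.tsv")
        peaks = pbm.peaks[:30]
        mm = build_match_matrix(motifs, peaks, tiny_genome)
        expected = set()
        for m in motifs:
            pwm = pfm_to_pwm(m)
            for p in peaks:
                seq = tiny_genome[p.chrom][p.start:p.end]
                for o in scan_sequence(pwm, seq, 0.8, peak_id=p.id):
                    expected.add((m.id, p.id, o.offset, o.strand))
        got = {(o.motif_id, o.peak_id, o.offset, o.strand) for o in mm.occurrences}
        assert got == expected


class TestGeneMapping:
    def _motifs(self):
        return [
            _motif_from_consensus("ACGT", "M1", "FOS"),
            _motif_from_consensus("ACGT", "M2", "FOS::JUN"),
            _motif_from_consensus("ACGT", "M3", "batf"),
            _motif_from_consensus("ACGT", "M4", "NOPE"),
        ]

    def test_expressed_filter_case_insensitive(self):
        kept = map_motifs_to_genes(self._motifs(), {"FOS", "BATF"})
        assert [(m.id, m.gene) for m in kept] == [("M1", "FOS"), ("M3", "BATF")]

    def test_dimer_policies(self):
        assert all("::" not in m.name
                   for m in map_motifs_to_genes(self._motifs(), {"FOS", "JUN"}))
        kept = map_motifs_to_genes(self._motifs(), {"FOS", "JUN"},
                                   dimer_policy="require_all")
        assert ("M2", "FOS") in [(m.id, m.gene) for m in kept]
        none_kept = map_motifs_to_genes(self._motifs(), {"FOS"},
                                        dimer_policy="require_all")
        assert "M2" not in [m.id for m in none_kept]

    def test_no_expressed_genes_gives_empty(self):
        assert map_motifs_to_genes(self._motifs(), set()) == []


def test_planted_motif_recovery_tiny(tiny_dataset, tiny_genome):
    """Scanning the generated genome with the generating PFMs recovers the
    plants with few extra calls."""
    from tfmeta import read_jaspar_pfms, read_peak_matrix
    _, gt, out = tiny_dataset
    motifs = read_jaspar_pfms(out / "motifs.jaspar")
    pbm = read_peak_matrix(out / "atac_matrix.mtx", out / "peaks.bed",
                           out / "atac_barcodes.tsv")
    mm = build_match_matrix(motifs, pbm.peaks, tiny_genome)
    planted = {(o.peak_id, o.offset) for o in gt.occurrences}
    found = {(o.peak_id, o.offset) for o in mm.occurrences}
    assert len(planted & found) / len(planted) >= 0.95
    assert len(found - planted) / len(planted) <= 0.05
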