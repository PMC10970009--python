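import numpy as np
import pytest
import scipy.sparse as sp

from tfmeta import (
    BiasModel,
    CellTypeMap,
    Fragment,
    Motif,
    PeakByCellMatrix,
    PeakRegion,
    build_insertion_index,
    fit_bias_model,
    footprint_matrix,
    footprint_score,
    footprint_vector,
)
from tfmeta.footprint import FootprintVector, flank_indices
from tfmeta.motif_scan import MatchMatrix, MotifOccurrence, encode_sequence


def _consensus_motif(L, mid="M1"):
    pfm = np.zeros((4, L))
    pfm[0, :] = 10.0
    return Motif(mid, "TF1", pfm)


def _world(L=8, occ_offset=250, n_cells=1):
    """One 500 bp peak at chr1:1000-1500 with one motif occurrence."""
    peak = PeakRegion("chr1", 1000, 1500, "p1")
    cells = [f"c{i}" for i in range(n_cells)]
    pbm = PeakByCellMatrix([peak], cells, sp.csr_matrix(np.ones((1, n_cells))))
    occ = MotifOccurrence("M1", "p1", occ_offset, "+", 0.0)
    return peak, pbm, occ


class TestInsertionIndex:
    def test_fragment_endpoints_with_multiplicity(self):
        idx = build_insertion_index([Fragment("chr1", 10, 60, "c1", 2)], ["c1"])
        mat = idx.matrices["chr1"]
        assert mat[10, 0] == 2 and mat[59, 0] == 2
        assert idx.total_insertions == 4

    def test_total_is_twice_count_sum(self):
        rng = np.random.default_rng(0)
        frags = [Fragment("chr1", int(s), int(s) + 20, "c1", int(c))
                 for s, c in zip(rng.integers(0, 500, 50), rng.integers(1, 4, 50))]
        idx = build_insertion_index(frags, ["c1"])
        assert idx.total_insertions == 2 * sum(f.count for f in frags)

    def test_half_open_window_queries(self):
        idx = build_insertion_index([Fragment("chr1", 10, 60, "c1", 2)], ["c1"])
        assert idx.window("chr1", 10, 60).sum() == 4
        assert idx.window("chr1", 11, 59).sum() == 0

    def test_sub2bp_fragments_skipped(self):
        idx = build_insertion_index(
            [Fragment("chr1", 5, 6, "c1", 1), Fragment("chr1", 10, 12, "c1", 1)], ["c1"])
        assert idx.n_skipped_fragments == 1
        assert idx.total_insertions == 2


class TestBiasModel:
    def test_uniform_model_weights_are_one(self):
        bias = BiasModel.uniform(k=6)
        codes = encode_sequence("ACGT" * 50)
        np.testing.assert_array_equal(bias.position_weights(codes), 1.0)

    def test_k_below_one_rejected(self):
        with pytest.raises(ValueError):
            BiasModel(k=0, weights=np.ones(1))
        with pytest.raises(ValueError):
            fit_bias_model({}, build_insertion_index([], ["c"]), [], k=0)

    def test_uniform_insertions_give_unit_weights(self):
        rng = np.random.default_rng(1)
        n = 20000
        codes = rng.integers(0, 4, n).astype(np.int8)
        peak = PeakRegion("chr1", 0, n, "p1")
        pos = rng.integers(3, n - 3, 100_000)
        frags = [Fragment("chr1", int(p), int(p) + 30, "c1", 1) for p in pos[::2]]
        idx = build_insertion_index(frags, ["c1"])
        bias = fit_bias_model({"chr1": codes}, idx, [peak], k=3)
        observed = bias.weights[bias.weights > bias.epsilon]
        assert np.median(observed) == pytest.approx(1.0, abs=0.1)

    def test_low_coverage_falls_back_to_uniform(self):
        codes = np.zeros(1000, dtype=np.int8)
        idx = build_insertion_index([Fragment("chr1", 10, 60, "c1", 1)], ["c1"])
        bias = fit_bias_model({"chr1": codes}, idx, [PeakRegion("chr1", 0, 1000, "p")], k=3)
        np.testing.assert_array_equal(bias.weights, 1.0)

    def test_planted_base_preference_recovered(self, tmp_path):
        """A generator configured to prefer insertions at A-centered sites
        yields ~2x weights for A-centered k-mers."""
        from tfmeta import SynthConfig, generate_dataset, read_fragments, read_peak_matrix
        cfg = SynthConfig(
            seed=3, n_cell_types=2, cells_per_type=10, n_motifs=4,
            n_peaks_per_class={"prom": 30, "enhD": 30, "exon": 0, "none": 0},
            plants_per_class={"prom": 2, "enhD": 2},
            baseline_insertion_rate=2e-2,      # dense coverage for the fit
            center_base_bias={"A": 2.0},
        )
        out = tmp_path / "biased"
        generate_dataset(cfg, out)
        from Bio import SeqIO
        genome = {r.id: encode_sequence(str(r.seq))
                  for r in SeqIO.parse(str(out / "genome.fa"), "fasta")}
        pbm = read_peak_matrix(out / "atac_matrix.mtx", out / "peaks.bed",
                               out / "atac_barcodes.tsv")
        idx = build_insertion_index(read_fragments(out / "fragments.tsv"), pbm.cells)
        bias = fit_bias_model(genome, idx, pbm.peaks, k=3)
        # center base of a 3-mer is position 1: code // 4 % 4
        centers = (np.arange(64) // 4) % 4
        w_a = np.median(bias.weights[centers == 0])
        w_other = np.median(bias.weights[centers != 0])
        assert w_a / w_other == pytest.approx(2.0, rel=0.25)


class TestFootprintVector:
    @pytest.mark.parametrize("L", [6, 8, 12])
    def test_length_law(self, L):
        peak, pbm, occ = _world(L=L)
        idx = build_insertion_index([Fragment("chr1", 1100, 1200, "c0", 1)], pbm.cells)
        fp = footprint_vector(_consensus_motif(L), [occ], idx, None, ["c0"], pbm)
        assert len(fp.values) - L == 500

    def test_window_edge_at_250bp(self):
        L = 8
        # 1000 bp peak so insertions can sit inside the peak but outside the
        # +/-250 bp window (keeping the depth normalizer nonzero)
        peak = PeakRegion("chr1", 1000, 2000, "p1")
        pbm = PeakByCellMatrix([peak], ["c0"], sp.csr_matrix(np.ones((1, 1))))
        occ = MotifOccurrence("M1", "p1", 600, "+", 0.0)
        motif_start = peak.start + occ.offset              # 1600; window [1350,1858)
        inside = build_insertion_index(
            [Fragment("chr1", motif_start - 250, 1901, "c0", 1)], pbm.cells)
        fp_in = footprint_vector(_consensus_motif(L), [occ], inside, None, ["c0"], pbm)
        assert fp_in.values[0] > 0
        assert np.count_nonzero(fp_in.values) == 1
        outside = build_insertion_index(
            [Fragment("chr1", motif_start - 251, 1901, "c0", 1)], pbm.cells)
        fp_out = footprint_vector(_consensus_motif(L), [occ], outside, None, ["c0"], pbm)
        assert not np.isnan(fp_out.values).any()
        assert (fp_out.values == 0).all()

    def test_minus_strand_window_reversed(self):
        L = 8
        peak, pbm, _ = _world(L=L)
        motif_start = peak.start + 250
        idx = build_insertion_index(
            [Fragment("chr1", motif_start - 250, motif_start - 100, "c0", 1)], pbm.cells)
        plus = MotifOccurrence("M1", "p1", 250, "+", 0.0)
        minus = MotifOccurrence("M1", "p1", 250, "-", 0.0)
        fp_plus = footprint_vector(_consensus_motif(L), [plus], idx, None, ["c0"], pbm)
        fp_minus = footprint_vector(_consensus_motif(L), [minus], idx, None, ["c0"], pbm)
        np.testing.assert_allclose(fp_minus.values, fp_plus.values[::-1])

    def test_zero_occurrences_gives_missing(self):
        _, pbm, _ = _world()
        idx = build_insertion_index([Fragment("chr1", 1100, 1200, "c0", 1)], pbm.cells)
        fp = footprint_vector(_consensus_motif(8), [], idx, None, ["c0"], pbm)
        assert np.isnan(fp.values).all()

    def test_uniform_bias_equals_no_bias(self):
        L = 6
        peak, pbm, occ = _world(L=L)
        idx = build_insertion_index(
            [Fragment("chr1", 1010, 1480, "c0", 1), Fragment("chr1", 1100, 1300, "c0", 2)],
            pbm.cells)
        weights = {"chr1": np.ones(2000)}
        fp_w = footprint_vector(_consensus_motif(L), [occ], idx, weights, ["c0"], pbm)
        fp_n = footprint_vector(_consensus_motif(L), [occ], idx, None, ["c0"], pbm)
        np.testing.assert_allclose(fp_w.values, fp_n.values)


class TestFootprintScore:
    def test_constant_vector_scores_its_value(self):
        L = 8
        fp = FootprintVector("M", "prom", np.full(500 + L, 3.5), L)
        assert footprint_score(fp) == pytest.approx(3.5)

    def test_score_depends_only_on_flanks(self):
        rng = np.random.default_rng(7)
        L = 10
        base = rng.random(500 + L)
        s0 = footprint_score(base.copy(), L)
        outside = base.copy()
        outside[99] += 5.0                      # position 100 (1-based): outside
        assert footprint_score(outside, L) == pytest.approx(s0)
        inside = base.copy()
        inside[209] += 5.0                      # position 210 (1-based): left flank
        assert footprint_score(inside, L) != pytest.approx(s0)

    def test_matches_index_set_oracle(self):
        rng = np.random.default_rng(8)
        L = 12
        values = rng.random(500 + L)
        idx = list(range(200, 250)) + list(range(250 + L, 300 + L))
        assert footprint_score(values, L) == pytest.approx(values[idx].mean())
        assert sorted(flank_indices(L).tolist()) == idx


class TestFootprintMatrix:
    def _setup(self, n_cells=4):
        L = 8
        peak, pbm, occ = _world(L=L, n_cells=n_cells)
        motif = _consensus_motif(L)
        mm = MatchMatrix(["M1"], ["p1"], sp.csr_matrix(np.ones((1, 1), dtype=np.int8)),
                         [occ])
        frags = [Fragment("chr1", 1150 + 10 * i, 1350 + 5 * i, f"c{i}", 1)
                 for i in range(n_cells)]
        idx = build_insertion_index(frags, pbm.cells)
        return motif, pbm, mm, idx

    def test_one_cell_per_type_equals_per_cell(self):
        motif, pbm, mm, idx = self._setup()
        ctmap = CellTypeMap({c: f"T{i}" for i, c in enumerate(pbm.cells)})
        res = footprint_matrix([motif], pbm, mm, idx, None, ctmap)
        for i, c in enumerate(pbm.cells):
            per_cell = res.per_cell.loc["M1", c]
            per_type = res.per_type.loc["M1", f"T{i}"]
            assert per_cell == pytest.approx(per_type, nan_ok=True)

    def test_cell_order_permutation_invariant(self):
        motif, pbm, mm, idx = self._setup()
        ctmap = CellTypeMap({c: "T0" if i < 2 else "T1" for i, c in enumerate(pbm.cells)})
        res1 = footprint_matrix([motif], pbm, mm, idx, None, ctmap)
        perm = [2, 0, 3, 1]
        pbm2 = PeakByCellMatrix(pbm.peaks, [pbm.cells[i] for i in perm],
                                pbm.counts[:, perm])
        mm2 = MatchMatrix(mm.motif_ids, mm.peak_ids, mm.matrix, mm.occurrences)
        res2 = footprint_matrix([motif], pbm2, mm2, idx, None, ctmap)
        assert res1.per_type.round(12).equals(res2.per_type.round(12))

    def test_missing_when_cell_has_no_insertions(self):
        motif, pbm, mm, _ = self._setup()
        idx = build_insertion_index([Fragment("chr1", 1150, 1350, "c0", 1)], pbm.cells)
        ctmap = CellTypeMap({c: "T0" for c in pbm.cells})
        res = footprint_matrix([motif], pbm, mm, idx, None, ctmap)
        assert not np.isnan(res.per_cell.loc["M1", "c0"])
        assert np.isnan(res.per_cell.loc["M1", "c1"])


def test_planted_footprints_separate_active_types(study_pipeline):
    """With planted depth 0.7 / boost 1.5, the pooled signal shows the
    flank > core shape and TFP ranks the active cell type first."""
    import pandas as pd
    cfg, gt, out = study_pipeline
    truth = gt.activity
    for tag in ("prom", "enhD"):
        tfp = pd.read_csv(out / f"footprint_{tag}_per_type.tsv", sep="\t", index_col=0)
        wins = total = 0
        for mid in tfp.index:
            act = truth.loc[mid]
            active = act.index[act > 0.5]
            if len(active) != 1 or tfp.loc[mid].isna().any():
                continue
            total += 1
            row = tfp.loc[mid].astype(float)
            if row[active[0]] > row.drop(active[0]).max():
                wins += 1
        assert total > 100
        assert wins / total >= 0.9

    # pooled vector: core depleted below flanks for the active type
    vec = pd.read_csv(out / "footprint_prom_vectors.tsv", sep="\t")
    mid = truth.index[0]
    active = truth.loc[mid].idxmax()
    v = vec[(vec.motif_id == mid) & (vec.cell_type == active)].sort_values("position")
    values = v.value.to_numpy()
    L = len(values) - 500
    core = values[250:250 + L].mean()
    flanks = np.concatenate([values[200:250], values[250 + L:300 + L]]).mean()
    assert core < flanks
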