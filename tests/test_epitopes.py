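"""Epitope prediction: windowing, pocket-profile scoring, calibration, CPR."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from asnscreen.epitopes import (
    CORE_LENGTH,
    POCKET_METHOD,
    WINDOW_LENGTH,
    BackgroundSet,
    ConfigurationError,
    PeptideWindow,
    PocketProfileMatrix,
    PredictionTableError,
    build_background,
    calibrate_percentile,
    consensus_rank,
    extract_cores,
    predict_epitopes,
    read_prediction_table,
    score_core,
    score_window,
    swissprot_frequencies,
    window_peptides,
)
from asnscreen.intake import CANONICAL_RESIDUES
from conftest import make_record
from oracles import best_frame_oracle, percentile_oracle


def zero_matrix(allele="HLA-DRB1*01:01"):
    return PocketProfileMatrix(allele=allele, weights=np.zeros((9, 20)))


def favoring_matrix(core: str, allele="HLA-DRB1*01:01", weight=1.0):
    w = np.zeros((9, 20))
    for p, res in enumerate(core):
        w[p, CANONICAL_RESIDUES.index(res)] = weight
    return PocketProfileMatrix(allele=allele, weights=w)


# ---------------------------------------------------------------------------
# windows
# ---------------------------------------------------------------------------

class TestWindowPeptides:
    def test_l_minus_k_plus_one(self):
        rec = make_record("A" * 17)
        wins = window_peptides(rec)
        assert [w.start for w in wins] == [1, 2, 3]

    def test_exact_length_single_window(self):
        rec = make_record("ACDEFGHIKLMNPQR")
        (win,) = window_peptides(rec)
        assert win.sequence == rec.sequence

    def test_typical_asparaginase_length_gives_318(self, rng):
        seq = "".join(rng.choice(list(CANONICAL_RESIDUES), 332))
        assert len(window_peptides(make_record(seq))) == 318

    def test_too_short_warns_and_returns_empty(self, caplog):
        with caplog.at_level("WARNING"):
            assert window_peptides(make_record("ACDEF")) == []
        assert "shorter" in caplog.text

    def test_windows_reslice(self, rng):
        seq = "".join(rng.choice(list(CANONICAL_RESIDUES), 40))
        rec = make_record(seq)
        for w in window_peptides(rec):
            assert seq[w.start - 1 : w.start - 1 + WINDOW_LENGTH] == w.sequence


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

class TestScoreCore:
    def test_zero_matrix(self):
        assert score_core(zero_matrix(), "ACDEFGHIK") == 0.0

    def test_all_alanine(self):
        m = PocketProfileMatrix(allele="x", weights=np.zeros((9, 20)))
        m.weights[:, CANONICAL_RESIDUES.index("A")] = 1.0
        assert score_core(m, "AAAAAAAAA") == 9.0

    def test_unit_weights_at_selected_positions(self):
        core = "ACDEFGHIK"
        w = np.zeros((9, 20))
        for p in (0, 3, 5, 8):  # positions 1,4,6,9
            w[p, CANONICAL_RESIDUES.index(core[p])] = 1.0
        m = PocketProfileMatrix(allele="x", weights=w)
        assert score_core(m, core) == 4.0

    def test_non_canonical_rejected(self):
        with pytest.raises(ValueError):
            score_core(zero_matrix(), "ACDEFGHIX")

    def test_linear_in_matrix(self, rng):
        w = rng.normal(size=(9, 20))
        core = "ACDEFGHIK"
        s1 = score_core(PocketProfileMatrix(allele="x", weights=w), core)
        s2 = score_core(PocketProfileMatrix(allele="x", weights=3 * w), core)
        assert s2 == pytest.approx(3 * s1)


class TestScoreWindow:
    def test_planted_offset_found(self):
        core = "CDEFGHIKL"
        m = favoring_matrix(core)
        win = PeptideWindow(protein_id="p", start=1,
                            sequence="AAA" + core + "AAA")
        raw, off = score_window(m, win)
        assert (raw, off) == (9.0, 3)

    def test_all_zero_tie_offset_zero(self):
        win = PeptideWindow(protein_id="p", start=1, sequence="ACDEFGHIKLMNPQR")
        assert score_window(zero_matrix(), win) == (0.0, 0)

    def test_equal_frames_smallest_offset(self):
        # frames at offsets 2 and 5 both score 1 via a shared residue weight
        w = np.zeros((9, 20))
        w[:, CANONICAL_RESIDUES.index("A")] = 1.0
        m = PocketProfileMatrix(allele="x", weights=w)
        win = PeptideWindow(protein_id="p", start=1, sequence="A" * 15)
        raw, off = score_window(m, win)
        assert off == 0

    def test_matches_frame_enumeration_oracle(self, rng):
        for _ in range(40):
            w = rng.normal(size=(9, 20))
            m = PocketProfileMatrix(allele="x", weights=w)
            seq = "".join(rng.choice(list(CANONICAL_RESIDUES), 15))
            win = PeptideWindow(protein_id="p", start=1, sequence=seq)
            raw, off = score_window(m, win)
            oracle_raw, oracle_off = best_frame_oracle(w, seq)
            assert raw == pytest.approx(oracle_raw)
            assert off == oracle_off


# ---------------------------------------------------------------------------
# percentile calibration
# ---------------------------------------------------------------------------

class TestCalibratePercentile:
    def bg(self, scores):
        return BackgroundSet(method=POCKET_METHOD, allele="x",
                             scores=np.array(scores, float), n=len(scores))

    def test_best_case_zero(self):
        assert calibrate_percentile(10, self.bg(range(1, 10))) == 0.0

    def test_strict_counting(self):
        assert calibrate_percentile(5, self.bg(range(1, 10))) == pytest.approx(
            100 * 4 / 9
        )

    def test_worst_case_hundred(self):
        assert calibrate_percentile(0, self.bg(range(1, 10))) == 100.0

    def test_ties_do_not_penalize(self):
        assert calibrate_percentile(5, self.bg([5, 5, 5])) == 0.0

    @given(
        st.lists(st.integers(-50, 50), min_size=1, max_size=200),
        st.integers(-60, 60),
    )
    def test_matches_counting_oracle(self, scores, raw):
        got = calibrate_percentile(raw, self.bg(scores))
        assert got == pytest.approx(percentile_oracle(raw, scores))

    def test_monotone_non_increasing(self, rng):
        bg = self.bg(rng.normal(size=500))
        raws = np.sort(rng.normal(size=50))
        pcts = [calibrate_percentile(r, bg) for r in raws]
        assert all(a >= b for a, b in zip(pcts, pcts[1:]))

    def test_empty_background_rejected(self):
        with pytest.raises(ValueError):
            BackgroundSet(method=POCKET_METHOD, allele="x",
                          scores=np.array([]), n=0)


class TestConsensusRank:
    def test_odd_median(self):
        assert consensus_rank([("a", 0.5), ("b", 1.5), ("c", 3.5)]) == 1.5

    def test_even_median(self):
        assert consensus_rank([("a", 1), ("b", 2), ("c", 3), ("d", 4)]) == 2.5

    def test_single_method_fixed_point(self):
        assert consensus_rank([("a", 0.8)]) == 0.8

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            consensus_rank([])

    @given(st.lists(st.floats(0, 100, allow_nan=False), min_size=1, max_size=9))
    def test_permutation_invariant_and_bounded(self, percentiles):
        per = [(f"m{i}", p) for i, p in enumerate(percentiles)]
        cpr = consensus_rank(per)
        assert consensus_rank(list(reversed(per))) == cpr
        assert min(percentiles) <= cpr <= max(percentiles)


# ---------------------------------------------------------------------------
# prediction + core extraction
# ---------------------------------------------------------------------------

class TestPredictEpitopes:
    def test_record_count(self, rng):
        seq = "".join(rng.choice(list(CANONICAL_RESIDUES), 30))
        rec = make_record(seq)
        mats = {f"AL{i}": favoring_matrix("ACDEFGHIK", f"AL{i}") for i in range(2)}
        bgs = {al: build_background(m, size=500, seed=3)
               for al, m in mats.items()}
        cons = predict_epitopes(rec, mats, bgs)
        assert len(cons) == 16 * 2

    def test_single_method_cpr_equals_percentile(self, rng):
        seq = "".join(rng.choice(list(CANONICAL_RESIDUES), 25))
        m = favoring_matrix("ACDEFGHIK")
        bg = build_background(m, size=500, seed=3)
        for rec in predict_epitopes(make_record(seq), {m.allele: m},
                                    {m.allele: bg}):
            assert rec.cpr == rec.per_method[0][1]
            assert rec.per_method[0][0] == POCKET_METHOD

    def test_planted_binder_lowers_cpr_for_its_allele(self, rng):
        core = "WWWWWWWWW"
        seq = ("".join(rng.choice(list("ACDEFGHIKLMNPQRSTVY"), 20))
               + core
               + "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVY"), 20)))
        rec = make_record(seq)
        strong = favoring_matrix(core, "A-strong", weight=5.0)
        other = favoring_matrix("CCCCCCCCC", "B-other", weight=5.0)
        mats = {m.allele: m for m in (strong, other)}
        bgs = {al: build_background(m, size=2000, seed=11)
               for al, m in mats.items()}
        cons = predict_epitopes(rec, mats, bgs)
        best = {al: min(c.cpr for c in cons if c.allele == al) for al in mats}
        assert best["A-strong"] < best["B-other"]

    def test_missing_background_is_config_error(self):
        m = zero_matrix()
        with pytest.raises(ConfigurationError):
            predict_epitopes(make_record("A" * 20), {m.allele: m}, {})

    def test_external_percentiles_enter_median(self, rng):
        from asnscreen.epitopes import AlleleScore

        seq = "".join(rng.choice(list(CANONICAL_RESIDUES), 15))
        rec = make_record(seq, "P1")
        m = zero_matrix()
        bg = build_background(m, size=100, seed=0)
        # zero matrix: every score ties the background, pocket percentile 0
        extra = [
            AlleleScore(
                window=PeptideWindow(protein_id="P1", start=1, sequence=seq),
                allele=m.allele, method=meth, raw=float("nan"), percentile=pct,
            )
            for meth, pct in (("nn_align", 40.0), ("smm_align", 80.0))
        ]
        (rec_out,) = predict_epitopes(rec, {m.allele: m}, {m.allele: bg}, extra)
        assert len(rec_out.per_method) == 3
        assert rec_out.cpr == 40.0  # median of {0, 40, 80}


class TestExtractCores:
    def _setup(self, rng, planted="MKVLHEWYA", n_flank=20):
        flank = "".join(rng.choice(list("ACDEFGIKLNPQRSTV"), n_flank))
        flank2 = "".join(rng.choice(list("ACDEFGIKLNPQRSTV"), n_flank))
        seq = flank + planted + flank2
        rec = make_record(seq, "PROT")
        m = favoring_matrix(planted, weight=8.0)
        bg = build_background(m, size=4000, seed=5)
        mats, bgs = {m.allele: m}, {m.allele: bg}
        cons = predict_epitopes(rec, mats, bgs)
        return rec, mats, bgs, cons

    def test_no_qualifying_window_empty(self, rng):
        rec = make_record("".join(rng.choice(list(CANONICAL_RESIDUES), 30)))
        m = zero_matrix()
        bg = BackgroundSet(method=POCKET_METHOD, allele=m.allele,
                           scores=np.arange(1000.0) + 1, n=1000)
        cons = predict_epitopes(rec, {m.allele: m}, {m.allele: bg})
        assert all(c.cpr == 100.0 for c in cons)
        assert extract_cores(cons, {m.allele: m}, {m.allele: bg}) == []

    def test_overlapping_windows_dedupe_to_one_core(self, rng):
        rec, mats, bgs, cons = self._setup(rng)
        cores = extract_cores(cons, mats, bgs)
        assert len(cores) == 1
        core = cores[0]
        assert core.start == 21
        assert core.core == "MKVLHEWYA"
        assert len(core.source_windows) >= 4  # pooled overlapping 15-mers
        assert core.core_cpr < 1.0
        assert rec.sequence[core.start - 1 : core.start + 8] == core.core

    def test_threshold_monotonicity(self, rng):
        rec, mats, bgs, cons = self._setup(rng)
        base = len(extract_cores(cons, mats, bgs, 2.0, 1.0))
        wider = len(extract_cores(cons, mats, bgs, 5.0, 3.0))
        tighter = len(extract_cores(cons, mats, bgs, 0.5, 0.2))
        assert tighter <= base <= wider

    def test_core_percentile_gate_is_independent(self, rng):
        """A window that passes the binder CPR cutoff still drops its core
        when the core's own percentile misses the stricter core cutoff."""
        planted = "MKVLHEWYA"
        flank = "".join(rng.choice(list("ACDEFGIKLNPQRSTV"), 20))
        flank2 = "".join(rng.choice(list("ACDEFGIKLNPQRSTV"), 20))
        rec = make_record(flank + planted + flank2, "PROT")
        m = favoring_matrix(planted, weight=1.0)  # planted frame raw = 9
        # hand-built background: 1.5% of scores sit above every query frame,
        # so the planted window's CPR is 1.5 — a binder, but its core misses
        # the default core gate of 1
        scores = np.concatenate([np.full(985, -100.0), np.full(15, 10.0)])
        bg = BackgroundSet(method=POCKET_METHOD, allele=m.allele,
                           scores=scores, n=1000)
        mats, bgs = {m.allele: m}, {m.allele: bg}
        cons = predict_epitopes(rec, mats, bgs)
        assert min(c.cpr for c in cons) == pytest.approx(1.5)
        assert 21 not in {c.start for c in extract_cores(cons, mats, bgs, 2.0, 1.0)}
        assert 21 in {c.start for c in extract_cores(cons, mats, bgs, 2.0, 2.0)}

    def test_thresholds_must_be_positive(self):
        with pytest.raises(ValueError):
            extract_cores([], {}, {}, 0, 1)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

class TestPredictionTable:
    HEADER = "protein_id\tstart\tpeptide\tallele\tmethod\tpercentile\n"
    ROW = "P1\t{start}\t{pep}\tHLA-DRB1*01:01\tnn_align\t{pct}\n"

    def _write(self, tmp_path, rows):
        p = tmp_path / "pred.tsv"
        p.write_text(self.HEADER + "".join(rows))
        return p

    def test_well_formed(self, tmp_path):
        rows = [self.ROW.format(start=i + 1, pep="ACDEFGHIKLMNPQR", pct=5.0 * i)
                for i in range(3)]
        scores = read_prediction_table(self._write(tmp_path, rows))
        assert len(scores) == 3
        assert scores[0].method == "nn_align"

    def test_out_of_range_percentile_names_row(self, tmp_path):
        rows = [self.ROW.format(start=1, pep="ACDEFGHIKLMNPQR", pct=101)]
        with pytest.raises(PredictionTableError, match="row 1"):
            read_prediction_table(self._write(tmp_path, rows))

    def test_short_peptide_rejected(self, tmp_path):
        rows = [self.ROW.format(start=1, pep="ACDEFGHIKLMNPQ", pct=1)]
        with pytest.raises(PredictionTableError, match="length 14"):
            read_prediction_table(self._write(tmp_path, rows))

    def test_missing_column(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("protein_id\tstart\n")
        with pytest.raises(PredictionTableError, match="missing"):
            read_prediction_table(p)


def test_matrix_tsv_round_trip(tmp_path, rng):
    m = PocketProfileMatrix(allele="HLA-DRB1*07:01",
                            weights=rng.normal(size=(9, 20)))
    p = tmp_path / "m.tsv"
    m.to_tsv(p)
    back = PocketProfileMatrix.from_tsv(p)
    assert back.allele == m.allele
    assert np.allclose(back.weights, m.weights, atol=1e-5)


def test_swissprot_frequencies_normalized():
    f = swissprot_frequencies()
    assert f.shape == (20,)
    assert f.sum() == pytest.approx(1.0)
    # leucine is the most common residue in Swiss-Prot-like compositions
    assert f[CANONICAL_RESIDUES.index("L")] == f.max()
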