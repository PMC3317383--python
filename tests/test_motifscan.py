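"""PSSM motif scoring, percentile ranking, and protein scanning."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ptmcrosstalk.motifscan import (
    RESIDUE_ORDER,
    WINDOW_LEN,
    KinaseMotif,
    NoScore,
    background_percentile,
    build_background,
    read_motif_tsv,
    scan_protein,
    score_window,
    window_at,
    write_motif_tsv,
)
from ptmcrosstalk.seqio import ProteinRecord
from ptmcrosstalk.synthetic import gen_protein


def motif_from(weights, name="m", targets="S"):
    return KinaseMotif(name=name, target_residues=frozenset(targets), weights=np.asarray(weights))


def indicator_motif(consensus: str, name="cons"):
    """1.0 for the consensus residue at each offset, 0 elsewhere."""
    w = np.zeros((WINDOW_LEN, 20))
    for i, res in enumerate(consensus):
        w[i, RESIDUE_ORDER.index(res)] = 1.0
    return motif_from(w, name=name, targets=consensus[WINDOW_LEN // 2])


CONSENSUS = "ACDEFGHSKLMNPQRVWAY"[:15]  # S at the center offset


class TestScoreWindow:
    def test_zero_matrix(self):
        m = motif_from(np.zeros((15, 20)))
        assert score_window(m, "AAAAAAASAAAAAAA") == 0.0

    def test_indicator_consensus_scores_window_length(self):
        m = indicator_motif(CONSENSUS)
        assert score_window(m, CONSENSUS) == 15.0

    def test_terminal_x_pads_score_zero(self):
        m = indicator_motif(CONSENSUS)
        assert score_window(m, "XXXXXXX" + CONSENSUS[7:]) == 8.0

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError, match="15"):
            score_window(indicator_motif(CONSENSUS), "SHORT")

    def test_untargetable_center_signals(self):
        with pytest.raises(NoScore):
            score_window(indicator_motif(CONSENSUS), "AAAAAAAGAAAAAAA")

    @settings(deadline=None, derandomize=True)
    @given(seed=st.integers(0, 5000))
    def test_matches_term_by_term_sum(self, seed):
        """Score equals an independent per-position summation."""
        rng = np.random.default_rng(seed)
        w = rng.normal(size=(15, 20))
        m = motif_from(w, targets="STY")
        window = "".join(rng.choice(list("AST"), size=15))
        window = window[:7] + "S" + window[8:]
        expected = sum(
            w[i, RESIDUE_ORDER.index(res)] for i, res in enumerate(window)
        )
        assert score_window(m, window) == pytest.approx(expected)

    def test_constant_shift_moves_score_by_15c(self):
        rng = np.random.default_rng(0)
        w = rng.normal(size=(15, 20))
        m1, m2 = motif_from(w), motif_from(w + 2.5)
        window = "ACDEFGHSKLMNPQR"
        assert score_window(m2, window) == pytest.approx(score_window(m1, window) + 15 * 2.5)


class TestBackgroundPercentile:
    def test_best_rank_is_zero(self):
        assert background_percentile(4.0, [1.0, 2.0, 3.0, 4.0]) == 0.0

    def test_worst_rank_is_one(self):
        assert background_percentile(0.5, [1.0, 2.0, 3.0, 4.0]) == 1.0

    def test_mid_rank(self):
        assert background_percentile(2.5, [1.0, 2.0, 3.0, 4.0]) == 0.5

    def test_ties_favor_candidate(self):
        assert background_percentile(3.0, [3.0, 3.0, 3.0]) == 0.0

    def test_empty_background_rejected(self):
        with pytest.raises(ValueError):
            background_percentile(1.0, [])

    def test_monotone_in_score(self):
        rng = np.random.default_rng(1)
        bg = rng.normal(size=200)
        scores = sorted(rng.normal(size=50))
        pcts = [background_percentile(s, bg) for s in scores]
        assert all(a >= b for a, b in zip(pcts, pcts[1:]))


class TestScanProtein:
    def test_no_targetable_residues(self):
        rec = ProteinRecord(id="r", sequence="ACDEFG")
        m = indicator_motif(CONSENSUS)
        assert scan_protein(rec, [m], {m.name: [1.0]}) == []

    def test_planted_consensus_found_uniquely(self):
        """A motif built as the indicator of a planted window hits only there."""
        rng = np.random.default_rng(7)
        bg_seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRVW"), size=200))
        rec = ProteinRecord(id="r", sequence=bg_seq[:90] + CONSENSUS + bg_seq[105:])
        m = indicator_motif(CONSENSUS)
        background = build_background(m, [gen_protein(500, seed=9)])
        hits = scan_protein(rec, [m], {m.name: background}, percentile_cutoff=0.0)
        assert [h.position for h in hits] == [98]  # 90 + 8: center of the insert
        assert hits[0].residue == "S"

    def test_sa_values_attached(self):
        rec = ProteinRecord(id="r", sequence="A" * 40 + CONSENSUS + "A" * 40)
        m = indicator_motif(CONSENSUS)
        bg = build_background(m, [gen_protein(300, seed=2)])
        hits = scan_protein(rec, [m], {m.name: bg}, sa_values={48: 1.3}, percentile_cutoff=0.0)
        assert hits and hits[0].sa == 1.3

    def test_motif_order_invariance(self):
        rec = gen_protein(150, seed=5)
        m1 = indicator_motif(CONSENSUS, name="a")
        m2 = indicator_motif(CONSENSUS[::-1][:7] + "S" + CONSENSUS[8:], name="b")
        bgs = {
            "a": build_background(m1, [gen_protein(300, seed=6)]),
            "b": build_background(m2, [gen_protein(300, seed=6)]),
        }
        h_ab = scan_protein(rec, [m1, m2], bgs, percentile_cutoff=0.5)
        h_ba = scan_protein(rec, [m2, m1], bgs, percentile_cutoff=0.5)
        assert h_ab == h_ba

    def test_shift_invariance_of_percentiles(self):
        """Adding a constant to all weights leaves background percentiles fixed.

        Holds for pad-free windows (every cell contributes), so targetable
        residues are kept at least 7 positions from the termini here.
        """
        rng = np.random.default_rng(11)
        w = rng.normal(size=(15, 20))

        def interior(seed):
            core = "".join(np.random.default_rng(seed).choice(list("AST"), size=120))
            return ProteinRecord(id=f"r{seed}", sequence="A" * 7 + core + "A" * 7)

        rec = interior(12)
        ref = [interior(13)]
        hits = {}
        for tag, shift in (("raw", 0.0), ("shifted", 3.7)):
            m = motif_from(w + shift, name="m", targets="ST")
            bg = build_background(m, ref)
            hits[tag] = scan_protein(rec, [m], {"m": bg}, percentile_cutoff=1.0)
        assert [(h.position, h.percentile) for h in hits["raw"]] == [
            (h.position, h.percentile) for h in hits["shifted"]
        ]


class TestMotifTsv:
    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(3)
        m = motif_from(rng.normal(size=(15, 20)).round(4), name="PKX", targets="ST")
        p = tmp_path / "motif.tsv"
        write_motif_tsv(m, p)
        back = read_motif_tsv(p)
        assert back.name == "PKX"
        assert back.target_residues == frozenset("ST")
        np.testing.assert_allclose(back.weights, m.weights)
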