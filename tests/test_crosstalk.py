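"""Crosstalk classification: truth-table oracle, selection filters, summaries."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ptmcrosstalk.crosstalk import (
    Classification,
    CrosstalkParams,
    ExperimentalAnnotation,
    SiteScore,
    annotate_sites,
    apply_selection_parameters,
    classify_site,
    kinase_crosstab,
    summarize_classifications,
)

C = Classification


def oracle(p_cat, g_cat, conserved):
    """Independent truth table for the classification rule.

    Written as an explicit enumeration over the categorical grid rather
    than by reusing the implementation's boolean algebra.
    """
    table = {
        # (phos, glyc): (classification if conserved, if not conserved)
        ("above", "above"): (C.YY_POSITIVE, C.YY_POSITIVE),
        ("above", "near"): (C.YY_FALSE_NEGATIVE, C.PHOSPHO_ONLY),
        ("above", "below"): (C.PHOSPHO_ONLY, C.PHOSPHO_ONLY),
        ("near", "above"): (C.YY_FALSE_NEGATIVE, C.GLYC_ONLY),
        ("near", "near"): (C.NONE, C.NONE),
        ("near", "below"): (C.NONE, C.NONE),
        ("below", "above"): (C.GLYC_ONLY, C.GLYC_ONLY),
        ("below", "near"): (C.NONE, C.NONE),
        ("below", "below"): (C.NONE, C.NONE),
    }
    return table[(p_cat, g_cat)][0 if conserved else 1]


def make_site(p, g, residue="S", pos=10, sa=None):
    return SiteScore(position=pos, residue=residue, phos=p, glyc=g, sa=sa)


class TestClassifySite:
    @pytest.mark.parametrize(
        "p_cat, g_cat, conserved",
        [
            (p, g, c)
            for p in ("above", "near", "below")
            for g in ("above", "near", "below")
            for c in (True, False)
        ],
    )
    def test_agrees_with_truth_table_oracle(self, p_cat, g_cat, conserved):
        """All 18 categorical cells match the independent oracle."""
        got = classify_site(make_site(p_cat, g_cat), conserved)
        assert got == oracle(p_cat, g_cat, conserved)

    @settings(deadline=None, derandomize=True)
    @given(
        phos=st.floats(0, 1, allow_nan=False),
        glyc=st.floats(0, 1, allow_nan=False),
        conserved=st.booleans(),
        epsilon=st.floats(0.01, 0.3),
    )
    def test_numeric_channels_match_their_categories(self, phos, glyc, conserved, epsilon):
        """Numeric potentials classify exactly as their binned categories do."""
        params = CrosstalkParams(epsilon=epsilon)
        site = make_site(phos, glyc)
        p_cat = site.phos_category(params)
        g_cat = site.glyc_category(params)
        assert classify_site(site, conserved, params) == classify_site(
            make_site(p_cat, g_cat), conserved, params
        )

    def test_tyrosine_has_no_glyc_channel(self):
        site = SiteScore(position=5, residue="Y", phos="above", glyc=None)
        assert classify_site(site, True) == C.PHOSPHO_ONLY
        assert classify_site(make_site("below", None, residue="Y"), True) == C.NONE
        with pytest.raises(ValueError):
            SiteScore(position=5, residue="Y", phos="above", glyc="above")

    def test_both_just_below_without_margin_is_none(self):
        params = CrosstalkParams(epsilon=0.0)
        site = make_site(0.49, 0.49)
        assert classify_site(site, conserved=False, params=params) == C.NONE

    def test_epsilon_monotonicity_of_fn_calls(self):
        """Growing epsilon never loses a false-negative Yin Yang call."""
        sites = [make_site(0.7, 0.5 - d / 100, pos=i + 1) for i, d in enumerate(range(1, 40))]
        previous = 0
        for eps in (0.05, 0.1, 0.2, 0.39):
            params = CrosstalkParams(epsilon=eps)
            n_fn = sum(
                classify_site(s, True, params) == C.YY_FALSE_NEGATIVE for s in sites
            )
            assert n_fn >= previous
            previous = n_fn
        assert previous > 0


class TestSelectionParameters:
    EV = [
        ExperimentalAnnotation(position=294, residue="S", kinases=("ERK1",)),
        ExperimentalAnnotation(position=32, residue="T", kinases=("AKT",)),
    ]

    def test_all_three_flags(self):
        site = make_site("above", "near", pos=294, sa=1.4)
        ann = apply_selection_parameters(site, C.YY_FALSE_NEGATIVE, True, self.EV)
        assert ann.ev_support and ann.conserved and ann.accessible
        assert ann.accepted
        assert "ERK1" in ann.kinases

    def test_buried_site(self):
        ann = apply_selection_parameters(make_site("above", "below", sa=0.4), C.PHOSPHO_ONLY, True, [])
        assert ann.accessible is False
        assert not ann.accepted

    def test_missing_sa_stays_positive(self):
        """Sites without an SA value are retained, accessibility unknown."""
        ann = apply_selection_parameters(make_site("above", "below"), C.PHOSPHO_ONLY, True, [])
        assert ann.accessible is None
        assert ann.accepted

    def test_absent_from_ev(self):
        ann = apply_selection_parameters(make_site("above", "below", pos=99), C.PHOSPHO_ONLY, True, self.EV)
        assert not ann.ev_support

    def test_residue_mismatch_is_an_error(self):
        site = make_site("above", "below", residue="T", pos=294)
        with pytest.raises(ValueError, match="residue"):
            apply_selection_parameters(site, C.PHOSPHO_ONLY, True, self.EV)


class TestSummaries:
    def test_empty_input(self):
        counts = summarize_classifications([])
        assert int(counts.to_numpy().sum()) == 0

    def test_duplicate_positions_rejected(self):
        anns = annotate_sites([make_site("above", "below", pos=5)] * 2, [5])
        with pytest.raises(ValueError, match="duplicate"):
            summarize_classifications(anns)

    def test_counts_are_conserved(self, foxo3_annotations):
        """Each site lands in exactly one class; totals match input sizes."""
        counts = summarize_classifications(foxo3_annotations)
        per_res = {r: sum(1 for a in foxo3_annotations if a.residue == r) for r in "STY"}
        for r in "STY":
            assert int(counts.loc[r].sum()) == per_res[r]

    def test_planted_synthetic_counts_recovered(self):
        from ptmcrosstalk.synthetic import gen_protein, gen_site_scores

        record = gen_protein(600, seed=7)
        planted = {C.YY_POSITIVE: 10, C.YY_FALSE_NEGATIVE: 4, C.PHOSPHO_ONLY: 20}
        sites, truth = gen_site_scores(record, planted, seed=7)
        anns = annotate_sites(sites, truth.conserved)
        counts = summarize_classifications(anns)
        assert int(counts["YY_POSITIVE"].sum()) == 10
        assert int(counts["YY_FALSE_NEGATIVE"].sum()) == 4
        assert int(counts["PHOSPHO_ONLY"].sum()) == 20


class TestKinaseCrosstab:
    def test_empty(self):
        assert kinase_crosstab([]) == {}

    def test_cdk5_sites(self, foxo3_annotations):
        """The five Cdk5-assigned serines, with Ser173 as the most exposed."""
        tab = kinase_crosstab(foxo3_annotations)
        assert [s["position"] for s in tab["Cdk5"]["sites"]] == [43, 173, 294, 355, 425]
        assert tab["Cdk5"]["max_sa_site"]["position"] == 173

    def test_akt_sites_include_known_and_novel(self, foxo3_annotations):
        tab = kinase_crosstab(foxo3_annotations)
        positions = {s["position"] for s in tab["AKT"]["sites"]}
        assert {253, 315, 32}.issubset(positions)  # experimentally established
        assert {12, 413}.issubset(positions)  # novel assignments

    def test_nonsite_assignment_excluded(self, foxo3_annotations, caplog):
        import logging

        with caplog.at_level(logging.WARNING):
            tab = kinase_crosstab(foxo3_annotations, {9999: ("PKA",)})
        assert tab == {}


class TestFoxo3Classifications:
    def test_akt_motif_serine_is_yin_yang(self, foxo3_annotations):
        by_pos = {a.position: a for a in foxo3_annotations}
        assert by_pos[253].classification == C.YY_POSITIVE

    def test_akt_threonine_is_false_negative(self, foxo3_annotations):
        by_pos = {a.position: a for a in foxo3_annotations}
        ann = by_pos[32]
        assert ann.classification == C.YY_FALSE_NEGATIVE
        assert ann.conserved and ann.ev_support

    def test_every_fn_site_is_conserved(self, foxo3_annotations):
        for a in foxo3_annotations:
            if a.classification == C.YY_FALSE_NEGATIVE:
                assert a.conserved

    def test_rerun_is_identical(self, foxo3_sites, foxo3_profile):
        conserved = {p: foxo3_profile.is_conserved(p) for p in range(1, 674)}
        a1 = annotate_sites(foxo3_sites, conserved)
        a2 = annotate_sites(foxo3_sites, conserved)
        assert a1 == a2
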