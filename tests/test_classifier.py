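"""Hierarchical classification rules and cohort-level reporting."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from cmslike import (
    BetaCateninScore,
    ClassifierModel,
    CohortConfig,
    SpotMarkerPanel,
    aggregate_bcat,
    aggregate_spot_calls,
    beta_catenin_call,
    classify_cohort,
    classify_patient,
    classify_spot,
    cohort_classification_report,
    generate_cohort,
    spot_epithelial_probability,
    zeb1_presence,
)


def _panel(cdx2=0, cdx2_pct=0.0, frmd6=0, frmd6_pct=0.0, htr2b=0, ker=0,
           ker_pct=0.0, zeb1_pct=0.0):
    return SpotMarkerPanel(cdx2, cdx2_pct, frmd6, frmd6_pct, htr2b, ker,
                           ker_pct, zeb1_pct)


EPITHELIAL = _panel(cdx2=3, cdx2_pct=90, ker=3, ker_pct=90)
MESENCHYMAL = _panel(cdx2=0, cdx2_pct=10, frmd6=3, frmd6_pct=80, htr2b=3,
                     ker=1, ker_pct=30, zeb1_pct=15)


class TestZeb1Presence:
    @pytest.mark.parametrize("pct,present", [(0.0, False), (1.9, False),
                                             (2.0, True), (50.0, True)])
    def test_two_percent_cutoff(self, pct, present):
        assert zeb1_presence(pct) is present

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            zeb1_presence(101.0)


class TestSpotProbability:
    def test_zero_features_zero_intercept_gives_half(self):
        model = ClassifierModel(intercept=0.0)
        assert spot_epithelial_probability(_panel(), model) == pytest.approx(0.5)

    def test_strongly_epithelial_panel(self):
        assert spot_epithelial_probability(EPITHELIAL, ClassifierModel()) > 0.9

    def test_strongly_mesenchymal_panel(self):
        assert spot_epithelial_probability(MESENCHYMAL, ClassifierModel()) < 0.1

    def test_zeb1_flip_never_raises_probability(self):
        model = ClassifierModel()
        assert model.coefficients["zeb1_present"] < 0
        for base in (EPITHELIAL, MESENCHYMAL, _panel(cdx2=2, cdx2_pct=50)):
            absent = _panel(base.cdx2_intensity, base.cdx2_pct,
                            base.frmd6_intensity, base.frmd6_pct,
                            base.htr2b_intensity, base.ker_intensity,
                            base.ker_pct, 0.0)
            present = _panel(base.cdx2_intensity, base.cdx2_pct,
                             base.frmd6_intensity, base.frmd6_pct,
                             base.htr2b_intensity, base.ker_intensity,
                             base.ker_pct, 50.0)
            assert (spot_epithelial_probability(present, model)
                    <= spot_epithelial_probability(absent, model))

    def test_panel_validation(self):
        with pytest.raises(ValueError):
            _panel(cdx2=4)
        with pytest.raises(ValueError):
            _panel(cdx2_pct=101.0)


class TestSpotCallAggregation:
    @pytest.mark.parametrize("prob,call", [(0.51, "E"), (0.49, "M"),
                                           (0.50, "E")])
    def test_threshold_with_tie_to_epithelial(self, prob, call):
        assert classify_spot(prob, 0.5) == call

    @pytest.mark.parametrize(
        "calls,expected",
        [
            (["E", "E", "M", "E"], "CMS2/3-like"),
            (["E", "E", "M", "M"], "inconclusive"),
            (["M"], "CMS4-like"),
            (["E", "M", "E"], "CMS2/3-like"),
        ],
    )
    def test_majority_vote(self, calls, expected):
        assert aggregate_spot_calls(calls) == expected

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate_spot_calls([])

    @given(st.lists(st.sampled_from(["E", "M"]), min_size=1, max_size=4),
           st.randoms(use_true_random=False))
    def test_order_independence(self, calls, rnd):
        shuffled = list(calls)
        rnd.shuffle(shuffled)
        assert aggregate_spot_calls(calls) == aggregate_spot_calls(shuffled)


class TestBetaCatenin:
    @pytest.mark.parametrize(
        "intensity,pct_cat,positive",
        [(2, 0, True), (1, 3, True), (1, 1, False), (0, 0, False),
         (3, 4, True), (0, 2, True)],
    )
    def test_two_in_either_rule(self, intensity, pct_cat, positive):
        assert beta_catenin_call(BetaCateninScore(intensity, pct_cat)) is positive

    @given(st.integers(0, 3), st.integers(0, 4))
    def test_monotone_in_both_scores(self, intensity, pct_cat):
        base = beta_catenin_call(BetaCateninScore(intensity, pct_cat))
        if intensity < 3:
            up = beta_catenin_call(BetaCateninScore(intensity + 1, pct_cat))
            assert up or not base
        if pct_cat < 4:
            up = beta_catenin_call(BetaCateninScore(intensity, pct_cat + 1))
            assert up or not base

    @pytest.mark.parametrize(
        "calls,expected",
        [([True, True, False], "positive"), ([True, False], "inconclusive"),
         ([False], "negative")],
    )
    def test_majority_consensus(self, calls, expected):
        assert aggregate_bcat(calls) == expected

    def test_score_validation(self):
        with pytest.raises(ValueError):
            BetaCateninScore(4, 0)
        with pytest.raises(ValueError):
            BetaCateninScore(0, 5)


class TestClassifyPatient:
    BCAT_NEG = [BetaCateninScore(0, 0)] * 3
    BCAT_POS = [BetaCateninScore(3, 4)] * 3

    def test_mmr_gate_precedes_everything(self):
        call = classify_patient("p1", True, [MESENCHYMAL] * 4, self.BCAT_POS)
        assert call.label == "CMS1-like"
        assert call.stage_provenance == "MMR gate"

    def test_epithelial_vote_bcat_negative_is_cms3(self):
        panels = [EPITHELIAL] * 3 + [MESENCHYMAL]
        call = classify_patient("p2", False, panels, self.BCAT_NEG)
        assert call.label == "CMS3-like"
        assert call.spot_calls == ["E", "E", "E", "M"]

    def test_epithelial_vote_bcat_positive_is_cms2(self):
        call = classify_patient("p3", False, [EPITHELIAL] * 4, self.BCAT_POS)
        assert call.label == "CMS2-like"

    def test_mesenchymal_vote_ignores_bcat(self):
        panels = [MESENCHYMAL, MESENCHYMAL, EPITHELIAL, MESENCHYMAL]
        call = classify_patient("p4", False, panels, self.BCAT_POS)
        assert call.label == "CMS4-like"

    def test_tied_vote_is_unclassified(self):
        panels = [EPITHELIAL, EPITHELIAL, MESENCHYMAL, MESENCHYMAL]
        call = classify_patient("p5", False, panels, self.BCAT_POS)
        assert call.label == "unclassified"
        assert call.stage_provenance == "inconclusive-at-vote"

    def test_tied_bcat_is_unclassified(self):
        call = classify_patient("p6", False, [EPITHELIAL] * 4,
                                [BetaCateninScore(3, 4), BetaCateninScore(0, 0)])
        assert call.label == "unclassified"
        assert call.stage_provenance == "inconclusive-at-bcat"

    def test_missing_spots_for_proficient_mmr(self):
        call = classify_patient("p7", False, [], self.BCAT_POS)
        assert call.label == "unclassified"
        assert call.stage_provenance == "missing-data"


class TestCohortReport:
    def test_published_cohort_arithmetic(self):
        labels = (["CMS1-like"] * 76 + ["CMS2-like"] * 168
                  + ["CMS3-like"] * 185 + ["CMS4-like"] * 52
                  + ["unclassified"] * 57)
        rep = cohort_classification_report(labels)
        assert rep["n_patients"] == 538
        assert rep["n_classified"] == 481
        assert round(rep["classified_fraction_pct"], 1) == 89.4
        assert round(rep["pct_of_classified"]["CMS1-like"], 1) == 15.8
        assert round(rep["pct_of_cohort"]["CMS1-like"], 1) == 14.1
        assert sum(rep["counts"].values()) == 538

    def test_all_unclassified(self):
        rep = cohort_classification_report(["unclassified"] * 5)
        assert rep["classified_fraction_pct"] == 0.0

    def test_degenerate_mmr_makes_cms1_equal_mmr_flag(self):
        cfg = CohortConfig(n_patients=120, seed=21,
                           mmr_deficiency_prob=(1.0, 0.0, 0.0, 0.0))
        patients, spots, bcat = generate_cohort(cfg)
        calls = classify_cohort(patients, spots, bcat)
        merged = patients.merge(calls, on="patient_id")
        assert ((merged["cms_label"] == "CMS1-like")
                == merged["mmr_deficient"]).all()
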