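import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

from nipiscreen.calls import (
    ControlsNotSeparable,
    PhenotypeCall,
    Thresholds,
    adhesion_category,
    adhesion_index,
    anchor_cutoff,
    call_enhancer_round1,
    call_nipi_round1,
    call_nipi_round2,
    call_peni_hipi,
    classify_epistasis,
    flag_developmental,
    select_adhesion_nipi,
)
from nipiscreen.screen_io import ValidationError

from conftest import make_normalized_well as nw

TH = Thresholds()
RACK1 = [nw(ngfp=0.6, ntof=0.8, clone="ctrl_rack1")] * 2


class TestNipiRound1:
    def test_twenty_percent_reduction_in_both_replicates(self):
        dup = [nw(ngfp=0.75), nw(ngfp=0.78, replicate=2)]
        assert call_nipi_round1(dup, RACK1, TH)

    def test_one_replicate_above_cutoff_fails(self):
        dup = [nw(ngfp=0.75), nw(ngfp=0.85, replicate=2)]
        assert not call_nipi_round1(dup, RACK1, TH)

    def test_worms_smaller_than_size_control_fail_the_guard(self):
        dup = [nw(ngfp=0.5, ntof=0.6), nw(ngfp=0.5, ntof=0.6, replicate=2)]
        assert not call_nipi_round1(dup, RACK1, TH)

    def test_increased_red_reporter_fails_the_guard(self):
        dup = [nw(ngfp=0.5, nred=1.4), nw(ngfp=0.5, nred=1.35, replicate=2)]
        assert not call_nipi_round1(dup, RACK1, TH)

    def test_missing_replicate_is_an_error(self):
        with pytest.raises(ValidationError, match="replicates"):
            call_nipi_round1([nw(ngfp=0.5)], RACK1, TH)

    def test_missing_size_controls_is_an_error(self):
        with pytest.raises(ValidationError, match="rack-1"):
            call_nipi_round1([nw(ngfp=0.5), nw(ngfp=0.5)], [], TH)


class TestEnhancerRound1:
    def test_thirty_percent_mean_increase_with_clean_guards(self):
        dup = [nw(ngfp=1.35, nred=1.05, ntof=1.0), nw(ngfp=1.35, replicate=2)]
        assert call_enhancer_round1(dup, TH)

    def test_red_reporter_increase_fails_guard(self):
        dup = [nw(ngfp=1.35, nred=1.40), nw(ngfp=1.35, nred=1.40, replicate=2)]
        assert not call_enhancer_round1(dup, TH)

    def test_below_threshold_mean_fails(self):
        dup = [nw(ngfp=1.25), nw(ngfp=1.25, replicate=2)]
        assert not call_enhancer_round1(dup, TH)


class TestAnchorCutoff:
    def test_midpoint_between_control_distributions(self):
        assert anchor_cutoff([2.0, 2.4], [1.0, 1.1]) == pytest.approx(1.55)

    def test_inseparable_controls_signal_assay_failure(self):
        with pytest.raises(ControlsNotSeparable):
            anchor_cutoff([1.2], [1.3])

    @given(
        pos=st.lists(st.floats(1.01, 100), min_size=1, max_size=8),
        neg=st.lists(st.floats(0.01, 100), min_size=1, max_size=8),
    )
    @settings(deadline=None)
    def test_valid_cutoff_separates_all_controls(self, pos, neg):
        if min(pos) <= max(neg):
            with pytest.raises(ControlsNotSeparable):
                anchor_cutoff(pos, neg)
        else:
            assume(min(pos) > max(neg) * (1 + 1e-9))  # resolvable in floats
            c = anchor_cutoff(pos, neg)
            assert max(neg) < c < min(pos)
            assert all(p >= c for p in pos) and all(n < c for n in neg)


def _quads(ngfps, condition, **kwargs):
    return [
        nw(ngfp=v, condition=condition, round_label=2, replicate=i + 1, **kwargs)
        for i, v in enumerate(ngfps)
    ]


class TestPeniHipi:
    def test_constitutive_expression_is_peni_not_hipi(self):
        peni, hipi = call_peni_hipi(
            _quads([3, 3, 3, 3], "infected"),
            _quads([3, 3, 3, 3], "noninfected"),
            peni_cutoff=2.0, hipi_cutoff=1.3,
        )
        assert (peni, hipi) == (True, False)

    def test_infection_only_elevation_is_hipi(self):
        peni, hipi = call_peni_hipi(
            _quads([1.5, 1.6, 1.4, 1.5], "infected"),
            _quads([1.0, 1.0, 1.0, 1.0], "noninfected"),
            peni_cutoff=2.0, hipi_cutoff=1.3,
        )
        assert (peni, hipi) == (False, True)

    def test_min_hits_rule(self):
        peni, _ = call_peni_hipi(
            _quads([1.0, 1.0, 1.0, 1.0], "infected"),
            _quads([3.0, 3.0, 1.0, 1.0], "noninfected"),
            peni_cutoff=2.0, hipi_cutoff=1.3, min_hits=3,
        )
        assert not peni

    @given(
        inf=st.lists(st.floats(0.1, 6), min_size=4, max_size=4),
        uninf=st.lists(st.floats(0.1, 6), min_size=4, max_size=4),
        peni_cut=st.floats(1.1, 4),
        hipi_cut=st.floats(1.1, 4),
    )
    @settings(deadline=None)
    def test_mutual_exclusivity_for_all_inputs(self, inf, uninf, peni_cut, hipi_cut):
        peni, hipi = call_peni_hipi(
            _quads(inf, "infected"), _quads(uninf, "noninfected"),
            peni_cut, hipi_cut,
        )
        assert not (peni and hipi)

    def test_wrong_replicate_count_is_an_error(self):
        with pytest.raises(ValidationError):
            call_peni_hipi(_quads([1, 1, 1], "infected"),
                           _quads([1, 1, 1, 1], "noninfected"), 2.0, 1.3)


class TestNipiRound2:
    def test_three_of_four_hits_with_median_below_cutoff(self):
        quads = _quads([0.5, 0.6, 0.9, 0.55], "infected")
        assert call_nipi_round2(quads, RACK1, TH)

    def test_two_of_four_hits_fails(self):
        quads = _quads([0.5, 0.6, 0.9, 0.95], "infected")
        assert not call_nipi_round2(quads, RACK1, TH)


class TestDevelopmental:
    def test_small_worms_flagged_against_explicit_cut(self):
        th = Thresholds(dev_ntof=0.7)
        assert flag_developmental(_quads([1, 1, 1, 1], "infected", ntof=0.5), th)

    def test_unremarkable_quadruplicates_not_flagged(self):
        assert not flag_developmental(_quads([1, 1, 1, 1], "infected"), TH, RACK1)

    def test_cut_anchors_to_size_control_when_unset(self):
        quads = _quads([1, 1, 1, 1], "infected", ntof=0.75)
        assert flag_developmental(quads, TH, RACK1)          # rack-1 ntof = 0.8
        assert not flag_developmental(quads, Thresholds(dev_ntof=0.7), RACK1)

    def test_reduced_red_reporter_flags(self):
        assert flag_developmental(_quads([1, 1, 1, 1], "infected", nred=0.5), TH)


class TestEpistasis:
    CONTROLS = {
        "gpa12star": [nw(ngfp=1.0, condition="gpa12star")],
        "osmotic": [nw(ngfp=1.0, condition="osmotic")],
        "irg1": [nw(ngfp=1.0, condition="irg1")],
    }

    def test_gpa12_abrogation_flags_g_clone(self):
        flags = classify_epistasis(
            [nw(ngfp=0.4, condition="gpa12star")], None, None, self.CONTROLS, TH
        )
        assert flags.g is True
        assert flags.o is None and flags.i is None  # assays absent: tri-state

    def test_irg1_induction_flags_i_clone(self):
        flags = classify_epistasis(
            None, None, [nw(ngfp=2.5, condition="irg1")], self.CONTROLS, TH
        )
        assert flags.i is True

    def test_osmotic_block(self):
        flags = classify_epistasis(
            None, [nw(ngfp=0.45, condition="osmotic")], None, self.CONTROLS, TH
        )
        assert flags.o is True
        below = classify_epistasis(
            None, [nw(ngfp=0.6, condition="osmotic")], None, self.CONTROLS, TH
        )
        assert below.o is False


class TestPhenotypeCallInvariants:
    def test_peni_hipi_exclusive(self):
        with pytest.raises(ValidationError):
            PhenotypeCall("c", peni=True, hipi=True)

    def test_round2_requires_round1(self):
        with pytest.raises(ValidationError):
            PhenotypeCall("c", round2_nipi=True)


class TestAdhesion:
    @pytest.mark.parametrize("count,category",
                             [(7, 0), (10, 0), (15, 1), (25, 1), (30, 2)])
    def test_spore_count_bins(self, count, category):
        assert adhesion_category(count) == category

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            adhesion_category(-1)

    @pytest.mark.parametrize("mouth,vulva,total,expected",
                             [(2, 3, 4, 0.625), (0, 0, 30, 0.0), (7, 7, 7, 1.0)])
    def test_adhesion_index_formula(self, mouth, vulva, total, expected):
        assert adhesion_index(mouth, vulva, total) == pytest.approx(expected)

    def test_index_bounds_and_errors(self):
        with pytest.raises(ValueError):
            adhesion_index(0, 0, 0)
        with pytest.raises(ValueError):
            adhesion_index(5, 0, 4)

    def test_selection_requires_both_duplicates_to_pass(self):
        controls = [0.3, 0.4]
        indices = {"a": (0.1, 0.12), "b": (0.1, 0.35), "c": (0.1, 0.1)}
        reductions = {"a": (0.6, 0.7), "b": (0.6, 0.7), "c": (0.4, 0.7)}
        assert select_adhesion_nipi(indices, controls, reductions) == {"a"}

    def test_missing_duplicate_is_an_error(self):
        with pytest.raises(ValidationError, match="duplicate"):
            select_adhesion_nipi({"a": (0.1,)}, [0.3], {"a": (0.6, 0.7)})
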