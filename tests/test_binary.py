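"""Binary coefficient estimators, growth-case classification, identifiability."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from miia import (
    BinaryCoefficientSet,
    DataCompletenessError,
    GrowthCase,
    GrowthPattern,
    UnidentifiableError,
    build_binary_set,
    classify_case,
    classify_flags,
    estimate_original,
    estimate_scaled,
    identifiability_summary,
    membership_key,
)
from conftest import build_observation_set

positive = st.floats(1e-3, 1e6, allow_nan=False, allow_infinity=False)


class TestEstimators:
    @pytest.mark.parametrize(
        "xiA, xiB, xjB, expected",
        [(2, 6, 4, 0.5), (5, 5, 3, 0.0), (1, 0.5, 2, -0.25)],
    )
    def test_original_examples(self, xiA, xiB, xjB, expected):
        assert estimate_original(xiA, xiB, xjB) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "xiA, xiB, xjB, expected",
        [(2, 6, 4, 1.0), (0, 0, 5, 0.0), (0, 3, 5, 0.6)],
    )
    def test_scaled_examples(self, xiA, xiB, xjB, expected):
        assert estimate_scaled(xiA, xiB, xjB) == pytest.approx(expected)

    def test_original_requires_axenic_growth(self):
        with pytest.raises(UnidentifiableError):
            estimate_original(0.0, 1.0, 1.0)

    @pytest.mark.parametrize("estimator", [estimate_original, estimate_scaled])
    def test_zero_influencer_unidentifiable(self, estimator):
        with pytest.raises(UnidentifiableError):
            estimator(1.0, 1.0, 0.0)

    @settings(max_examples=100, derandomize=True)
    @given(positive, st.floats(0, 1e6), positive)
    def test_scaling_consistency(self, xiA, xiB, xjB):
        """b = x_iA * a whenever both estimators apply (same sign follows)."""
        a = estimate_original(xiA, xiB, xjB)
        b = estimate_scaled(xiA, xiB, xjB)
        assert b == pytest.approx(xiA * a, rel=1e-12, abs=1e-300)
        assert np.sign(a) == np.sign(b)


class TestClassification:
    def test_total_over_all_flag_combinations(self):
        seen = set()
        for flags in itertools.product([False, True], repeat=4):
            cls_ = classify_flags(*flags)
            seen.add(cls_.case)
            # identifiability always follows the flags, never the label
            gAi, gAj, gBi, gBj = flags
            assert cls_.original_ok == (gAi and gBi and gBj)
            assert cls_.scaled_ok == gBj
        assert seen == set(GrowthCase)

    def test_both_estimators_when_all_grow(self):
        cls_ = classify_flags(True, True, True, True)
        assert cls_.case is GrowthCase.I
        assert cls_.original_ok and cls_.scaled_ok and not cls_.excluded

    def test_scaled_only_without_axenic_growth(self):
        cls_ = classify_flags(False, True, True, True)
        assert cls_.case is GrowthCase.V
        assert not cls_.original_ok and cls_.scaled_ok

    def test_neither_when_influencer_absent_in_binary(self):
        for gAi in (False, True):
            cls_ = classify_flags(gAi, True, True, False)
            assert not cls_.original_ok and not cls_.scaled_ok
            assert cls_.case is GrowthCase.IV

    def test_excluded_cases_are_the_rare_extinctions(self):
        assert classify_flags(True, True, False, True).case is GrowthCase.III
        assert classify_flags(True, True, False, False).case is GrowthCase.VIII
        assert classify_flags(True, True, False, True).excluded
        assert classify_flags(True, True, False, False).excluded

    def test_classify_case_requires_cultures(self):
        gp = GrowthPattern({("A", "A"): True})
        with pytest.raises(DataCompletenessError):
            classify_case(gp, "A", "B")


class TestBuild:
    def test_kato_original_identifies_4_of_12(self, kato_obs):
        bset = build_binary_set(kato_obs, form="original")
        summary = identifiability_summary(bset)
        assert summary["n_estimated"] == 4
        assert summary["n_total"] == 12

    def test_kato_scaled_identifies_8_of_12(self, kato_obs):
        bset = build_binary_set(kato_obs, form="scaled")
        summary = identifiability_summary(bset)
        assert summary["n_estimated"] == 8
        assert set(bset.unidentifiable_pairs()) == {
            ("CS", "CT"),
            ("CT", "CS"),
            ("PT", "CT"),
            ("BA", "CT"),
        }

    def test_all_growth_has_no_unidentifiable(self, wang_obs):
        for form in ("original", "scaled"):
            bset = build_binary_set(wang_obs, form=form)
            assert not bset.unidentifiable_pairs()
            assert identifiability_summary(bset)["percent_estimated"] == 100.0

    def test_two_species_case_i_summary(self):
        oset = build_observation_set(
            {
                ("A",): {"A": 2.0},
                ("B",): {"B": 3.0},
                ("A", "B"): {"A": 4.0, "B": 5.0},
            }
        )
        summary = identifiability_summary(build_binary_set(oset))
        assert summary["percent_estimated"] == 100.0
        assert summary["cases"] == {"I": 2}

    def test_missing_binary_culture_reported(self):
        oset = build_observation_set(
            {("A",): {"A": 1.0}, ("B",): {"B": 1.0}}
        )
        with pytest.raises(DataCompletenessError, match="A\\+B"):
            build_binary_set(oset)

    def test_scaled_value_for_species_dying_in_binary(self):
        # i grows alone (2.0) but not with j; its scaled coefficient is
        # (0 - x_iA)/x_jB, still estimable
        oset = build_observation_set(
            {
                ("I",): {"I": 2.0},
                ("J",): {"J": 1.0},
                ("I", "J"): {"I": 0.0, "J": 4.0},
            }
        )
        bset = build_binary_set(oset, form="scaled")
        assert bset.coefficients[("I", "J")].value == pytest.approx(-0.5)


class TestSerialization:
    def test_tsv_roundtrip(self, kato_obs, tmp_path):
        bset = build_binary_set(kato_obs, form="scaled")
        path = tmp_path / "binary.tsv"
        bset.to_tsv(path)
        loaded = BinaryCoefficientSet.from_tsv(path)
        assert loaded.form == bset.form
        assert loaded.roster == bset.roster
        for pair in bset.pairs:
            a, b = bset.coefficients[pair], loaded.coefficients[pair]
            assert a.status == b.status and a.case == b.case
            if a.value is None:
                assert b.value is None
            else:
                assert b.value == pytest.approx(a.value, rel=1e-11)

    def test_strict_value_lookup_names_pair(self, kato_obs):
        bset = build_binary_set(kato_obs, form="scaled")
        with pytest.raises(UnidentifiableError, match="CT<-CS"):
            bset.value("CT", "CS", strict=True)

    def test_assignments_fill_unidentifiable(self, kato_obs):
        bset = build_binary_set(kato_obs, form="scaled")
        assert bset.value("CT", "CS") == 0.0
        assert bset.value("CT", "CS", {("CT", "CS"): 2.5}) == 2.5
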