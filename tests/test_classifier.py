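"""The decision workflow: exclusions, marker selection, tiered calls."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methylfluid.classifier import classify, exclude_by_pretests, select_markers
from methylfluid.cohort import MixtureSpec, derive_pretests, mix_profile
from methylfluid.panel import (
    MARKER_ORDER,
    NASAL_PAIR_LABEL,
    BodyFluid,
    PreTestPanel,
)

from conftest import pretests

ALL_NEG = pretests("negative", "negative", "negative")


class TestExcludeByPretests:
    def test_all_negative_excludes_five_fluids(self):
        assert exclude_by_pretests(ALL_NEG) == {
            BodyFluid.PERIPHERAL_BLOOD,
            BodyFluid.MENSTRUAL_BLOOD,
            BodyFluid.NASAL_BLOOD,
            BodyFluid.SALIVA,
            BodyFluid.SPERM_SECRETION,
        }

    def test_only_saliva_negative(self):
        panel = pretests("positive", "negative", "positive")
        assert exclude_by_pretests(panel) == {BodyFluid.SALIVA}

    def test_not_done_excludes_nothing(self):
        assert exclude_by_pretests(pretests()) == set()


class TestSelectMarkers:
    @pytest.mark.parametrize(
        "blood, saliva, sperm, expected",
        [
            ("negative", "negative", "negative", {"V2", "N27SE"}),
            ("positive", "negative", "positive", {"NB21", "B7", "MB4", "N27SE"}),
            ("negative", "positive", "negative", {"SA4", "V2", "N27SE"}),
            ("not_done", "not_done", "not_done", set(MARKER_ORDER)),
        ],
    )
    def test_pretest_constellations(self, blood, saliva, sperm, expected):
        chosen = {m.short_name for m in select_markers(pretests(blood, saliva, sperm))}
        assert chosen == expected


class TestCasework:
    def test_bed_sheet_stain_is_nasal_secretion(self):
        result = classify({"V2": 8, "N27SE": 29}, ALL_NEG)
        assert result.called_fluids == {"nasal_secretion"}
        assert not result.mixture and not result.undetermined

    def test_handkerchief_stain_is_menstrual_sperm_mixture(self):
        result = classify(
            {"NB21": 90, "B7": 38, "MB4": 20, "N27SE": 51},
            pretests("positive", "negative", "positive"),
        )
        assert result.called_fluids == {"menstrual_blood", "sperm_secretion"}
        assert result.mixture

    def test_towel_stain_is_saliva_plus_vaginal(self):
        result = classify(
            {"SA4": 28, "V2": 43, "N27SE": 17},
            pretests("negative", "positive", "negative"),
        )
        assert result.components == {"saliva", "vaginal_secretion"}
        assert result.mixture

    def test_nontarget_profile_is_undetermined(self):
        # typical non-target methylation everywhere, everything pre-excluded
        result = classify(
            {"NB21": 85, "B7": 30, "MB4": 7, "SA4": 7, "V2": 10, "N27SE": 20},
            ALL_NEG,
        )
        assert result.undetermined

    def test_high_n27se_with_positive_sperm_pretest(self):
        result = classify({"N27SE": 95}, pretests(sperm="positive"))
        assert "sperm_secretion" in result.called_fluids


class TestCallComposition:
    def test_nasal_pair_disambiguated_by_blood_pretest(self):
        low_nb21 = {"NB21": 50}
        assert classify(low_nb21, pretests(blood="positive")).called_fluids == {"nasal_blood"}
        assert classify(low_nb21, pretests(blood="negative")).called_fluids == {"nasal_secretion"}
        assert classify(low_nb21, pretests()).called_fluids == {NASAL_PAIR_LABEL}

    def test_b7_above_cutoff_calls_pure_peripheral_blood(self):
        result = classify({"B7": 88}, pretests(blood="positive"))
        assert result.called_fluids == {"peripheral_blood"}

    def test_saliva_full_supersedes_partial(self):
        result = classify({"SA4": 40}, pretests(saliva="positive"))
        assert result.called_fluids == {"saliva"}
        assert result.partial_components == set()

    def test_vaginal_tract_band_without_blood_exclusion(self):
        result = classify({"V2": 30}, pretests(blood="positive"))
        assert result.partial_components == {"vaginal_tract_secretion"}

    def test_sperm_pretest_contradicted_by_low_n27se(self):
        result = classify({"N27SE": 10}, pretests("negative", "negative", "positive"))
        assert "sperm_secretion" not in result.components
        assert any("contradicted" in w for w in result.warnings)

    def test_menstrual_ambiguity_flag(self):
        # blood-positive stain, B7 below 80, V2 above 25: menstrual blood or
        # a peripheral-blood/vaginal mixture
        result = classify(
            {"B7": 50, "MB4": 25, "V2": 45},
            pretests(blood="positive", saliva="negative", sperm="negative"),
        )
        assert "menstrual_blood" in result.called_fluids
        assert result.ambiguity_flags

    def test_excluded_fluid_never_called_despite_tier(self):
        # sperm-range N27SE but a confirmed-negative sperm test: exclusion wins
        result = classify({"N27SE": 90}, pretests("negative", "negative", "negative"))
        assert "sperm_secretion" not in result.components
        assert any("suppressed" in w for w in result.warnings)

    def test_missing_markers_raise_coverage_warning(self):
        result = classify({"V2": 8}, ALL_NEG)
        assert any("not evaluated" in w for w in result.warnings)

    def test_out_of_range_value_and_unknown_marker(self):
        with pytest.raises(ValueError):
            classify({"V2": 105}, ALL_NEG)
        with pytest.raises(KeyError):
            classify({"XX9": 10}, ALL_NEG)


class TestBoundaryMonotonicity:
    @pytest.mark.parametrize("value", [75.01, 80, 90, 99.5])
    def test_sperm_call_stable_above_threshold(self, value):
        result = classify({"N27SE": value}, pretests(sperm="positive"))
        assert "sperm_secretion" in result.called_fluids

    @pytest.mark.parametrize("value", [67.0, 70, 85, 100])
    def test_nb21_above_cutoff_never_creates_nasal_call(self, value):
        result = classify({"NB21": value}, pretests(blood="positive"))
        assert result.called_fluids & {"nasal_blood", "nasal_secretion", NASAL_PAIR_LABEL} == set()


class TestSyntheticBehaviour:
    def test_reference_mean_profiles_called_correctly(self, noiseless_distributions):
        """At the reference means every strongly-separated fluid is called:
        sperm (N27SE 90.39 > 75), saliva (SA4 38.98 > 35), vaginal secretion
        (V2 53.55 > 50), peripheral blood (B7 87.43 > 80), menstrual blood
        (MB4 20.39 > 18 with sperm negative), nasal secretion (N27SE 31.40
        inside the fully relaxed band)."""
        expected = {
            BodyFluid.SPERM_SECRETION: {"sperm_secretion"},
            BodyFluid.SALIVA: {"saliva"},
            BodyFluid.VAGINAL_SECRETION: {"vaginal_secretion"},
            BodyFluid.PERIPHERAL_BLOOD: {"peripheral_blood"},
            BodyFluid.MENSTRUAL_BLOOD: {"menstrual_blood"},
            BodyFluid.NASAL_SECRETION: {"nasal_secretion"},
        }
        for fluid, want in expected.items():
            spec = MixtureSpec.single(fluid)
            profile = {
                m: mix_profile(spec, m, 0, noiseless_distributions)
                for m in MARKER_ORDER
            }
            result = classify(profile, derive_pretests(spec))
            assert result.called_fluids == want, fluid

    def test_known_nasal_mixture_blind_spot(self):
        """Nasal mixtures with vaginal or sperm components run 71–95% at
        NB21 and are not recognisable as nasal from that marker."""
        for value in (71, 80, 95):
            result = classify(
                {"NB21": value}, pretests("positive", "negative", "negative")
            )
            assert not (
                result.components
                & {"nasal_secretion", "nasal_blood", NASAL_PAIR_LABEL}
            )

    @given(
        values=st.lists(st.floats(0, 100, allow_nan=False), min_size=6, max_size=6),
        states=st.lists(
            st.sampled_from(["positive", "negative", "not_done"]),
            min_size=3, max_size=3,
        ),
    )
    @settings(deadline=None, max_examples=120)
    def test_pretest_exclusion_invariant(self, values, states):
        """No pre-test-excluded fluid ever appears among the components,
        for any profile and pre-test constellation."""
        panel = pretests(*states)
        profile = dict(zip(MARKER_ORDER, values))
        result = classify(profile, panel)
        excluded = {f.value for f in exclude_by_pretests(panel)}
        assert not (result.components & excluded)
        # structural invariants of the result object
        assert result.undetermined == (not result.components)
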