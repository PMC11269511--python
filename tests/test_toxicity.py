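"""Corrected mortality, reduction coefficient, IOBC and persistence classes."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from demotox._util import round_half_up
from demotox.cohort import Cohort, CohortRecord, ExposureRoute, Sex
from demotox.synthetic import preset_configs, simulate_cohort
from demotox.toxicity import (
    IOBCClass,
    MortalityCounts,
    PersistenceClass,
    ReductionInputs,
    ResidueSeries,
    Scheme,
    ToxicityAssessment,
    UndefinedCorrectionError,
    assess,
    assess_persistence,
    classify_iobc,
    corrected_mortality,
    corrected_mortality_pct,
    reduction_coefficient,
    score_cohort_pair,
)


class TestCorrectedMortality:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            (MortalityCounts(50, 47, 50, 4), 91.49),   # heavy kill
            (MortalityCounts(50, 47, 50, 7), 85.11),
            (MortalityCounts(50, 47, 50, 8), 82.98),
            (MortalityCounts(50, 47, 50, 47), 0.0),    # same ratio as control
            (MortalityCounts(50, 47, 50, 0), 100.0),   # total kill
        ],
    )
    def test_henderson_tilton(self, counts, expected):
        assert round_half_up(corrected_mortality(counts), 2) == expected

    def test_total_control_mortality_undefined(self):
        with pytest.raises(UndefinedCorrectionError):
            corrected_mortality(MortalityCounts(50, 0, 50, 10))

    def test_abbott_form_matches_equal_before_counts(self):
        counts = MortalityCounts(50, 45, 50, 20)
        via_counts = corrected_mortality(counts)
        via_pct = corrected_mortality_pct(10.0, 60.0)  # 45/50 and 20/50 alive
        assert via_counts == pytest.approx(via_pct)

    def test_clamped_when_treated_outlives_control(self):
        assert corrected_mortality(MortalityCounts(50, 40, 50, 45)) == 0.0


class TestReductionCoefficient:
    @pytest.mark.parametrize(
        "mc, fec_t, viab_t, ndigits, expected",
        [
            (70.0, 3.5, 84.4, 2, 96.74),
            (68.0, 8.3, 93.8, 2, 90.84),
            (52.0, 5.9, 95.0, 1, 90.1),
            (82.0, 2.5, 87.5, 1, 98.6),
        ],
    )
    def test_adult_two_factor_form(self, mc, fec_t, viab_t, ndigits, expected):
        inputs = ReductionInputs(mc=mc, fecundity_t=fec_t, fecundity_c=27.6,
                                 viability_t=viab_t, viability_c=98.5)
        assert round_half_up(reduction_coefficient(inputs), ndigits) == expected

    def test_no_effect_at_all(self):
        inputs = ReductionInputs(0.0, 10.0, 10.0, 90.0, 90.0,
                                 longevity_t=12.0, longevity_c=12.0)
        assert reduction_coefficient(inputs, include_longevity=True) == 0.0

    def test_total_mortality_is_absorbing(self):
        inputs = ReductionInputs(100.0, 50.0, 1.0, 100.0, 1.0)
        assert reduction_coefficient(inputs) == 100.0

    def test_longevity_required_for_three_ratio_form(self):
        inputs = ReductionInputs(10.0, 5.0, 10.0, 90.0, 95.0)
        with pytest.raises(ValueError, match="longevit"):
            reduction_coefficient(inputs, include_longevity=True)

    def test_equals_mc_when_ratios_are_one(self):
        inputs = ReductionInputs(43.7, 9.0, 9.0, 88.0, 88.0,
                                 longevity_t=7.0, longevity_c=7.0)
        assert reduction_coefficient(inputs, include_longevity=True) == pytest.approx(43.7)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        mc=st.floats(0, 100),
        f=st.floats(0.01, 3),
        v=st.floats(0.01, 2),
        lon=st.floats(0.01, 2),
        bump=st.floats(0.01, 1),
    )
    def test_monotone_in_mortality_and_ratios(self, mc, f, v, lon, bump):
        def ex(mc_, f_, v_, l_):
            return reduction_coefficient(
                ReductionInputs(mc_, f_, 1.0, v_, 1.0,
                                longevity_t=l_, longevity_c=1.0),
                include_longevity=True,
            )

        base = ex(mc, f, v, lon)
        assert ex(min(100.0, mc + bump), f, v, lon) >= base  # worse mortality
        assert ex(mc, f + bump, v, lon) <= base              # better fecundity
        assert ex(mc, f, v + bump, lon) <= base              # better viability
        assert ex(mc, f, v, lon + bump) <= base              # better longevity


class TestClassification:
    @pytest.mark.parametrize(
        "ex, expected",
        [
            (0.0, "I"), (29.99, "I"), (30.0, "II"), (75.91, "II"), (78.75, "II"),
            (79.5, "II"), (80.0, "III"), (83.6, "III"), (86.82, "III"),
            (90.84, "III"), (96.74, "III"), (99.0, "III"), (99.5, "IV"),
            (100.0, "IV"),
        ],
    )
    def test_lab_scheme_bands(self, ex, expected):
        assert classify_iobc(ex, Scheme.lab).value == expected

    @pytest.mark.parametrize(
        "ex, expected",
        [
            (7.4, "I"), (16.4, "I"), (17.89, "I"), (24.2, "I"), (25.0, "II"),
            (39.0, "II"), (44.5, "II"), (50.0, "II"), (50.5, "III"),
            (57.9, "III"), (70.99, "III"), (72.45, "III"), (74.4, "III"),
            (75.0, "III"), (75.1, "IV"), (95.3, "IV"), (100.0, "IV"),
        ],
    )
    def test_extended_lab_scheme_bands(self, ex, expected):
        assert classify_iobc(ex, Scheme.extended_lab).value == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_iobc(101.0, Scheme.lab)


def _series(treatment, day_to_class):
    assessments = {
        d: ToxicityAssessment(ex=10.0 if c == "I" else 90.0,
                              scheme=Scheme.extended_lab,
                              iobc_class=IOBCClass(c))
        for d, c in day_to_class.items()
    }
    return ResidueSeries(treatment, assessments)


class TestPersistence:
    @pytest.mark.parametrize(
        "day_to_class, expected_class, expected_day",
        [
            ({4: "I"}, "A", 4),                                  # short-lived
            ({4: "III", 10: "I"}, "B", 10),                      # slight
            ({4: "III", 10: "III", 20: "I"}, "C", 20),           # moderate
            ({4: "IV", 10: "IV", 20: "IV", 31: "IV"}, "D", None),  # persistent
        ],
    )
    def test_published_patterns(self, day_to_class, expected_class, expected_day):
        res = assess_persistence(_series("x", day_to_class))
        assert res.persistence_class.value == expected_class
        assert res.days_to_harmless == expected_day

    def test_nonmonotone_recovery_uses_last_transition(self):
        with pytest.warns(UserWarning, match="non-monotone"):
            res = assess_persistence(
                _series("x", {4: "I", 10: "III", 20: "I", 31: "I"})
            )
        assert res.days_to_harmless == 20
        assert res.persistence_class is PersistenceClass.C
        assert res.warnings

    def test_harmless_only_after_observation_window_is_persistent(self):
        res = assess_persistence(_series("x", {4: "IV", 31: "IV"}))
        assert res.persistence_class is PersistenceClass.D


class TestScoreCohortPair:
    def test_self_comparison_is_harmless(self):
        cohort = simulate_cohort(preset_configs()["control-like"].replace(n=100, seed=5))
        a = score_cohort_pair(cohort, cohort, variant="egg")
        assert a.ex == 0.0
        assert a.iobc_class is IOBCClass.I

    def test_total_kill_is_class_iv(self):
        control = simulate_cohort(preset_configs()["control-like"].replace(n=50, seed=6))
        dead = Cohort(
            "dead",
            [CohortRecord(f"d{i}", "dead", death_age=4) for i in range(50)],
            n_initial=50,
        )
        a = score_cohort_pair(control, dead, variant="egg")
        assert a.ex == 100.0
        assert a.iobc_class is IOBCClass.IV

    def test_stressor_scores_clearly_harmful(self):
        control = simulate_cohort(preset_configs()["control-like"].replace(n=300, seed=7))
        stressed = simulate_cohort(preset_configs()["stressor-like"].replace(n=300, seed=8))
        a = score_cohort_pair(control, stressed, variant="egg")
        assert a.ex > 70.0

    def test_adult_variant_runs_on_adult_route(self):
        presets = preset_configs()
        adult_cfg = presets["control-like"].replace(
            n=80, seed=9, exposure_route=ExposureRoute.topical_adult,
            treatment="adult-ctrl",
        )
        control = simulate_cohort(adult_cfg)
        treated = simulate_cohort(
            presets["stressor-like"].replace(
                n=80, seed=10, exposure_route=ExposureRoute.topical_adult,
                treatment="adult-trt",
            )
        )
        a = score_cohort_pair(control, treated, variant="adult")
        assert 0.0 <= a.ex <= 100.0
        assert a.r3 is None  # two-factor form for adult exposure

    def test_route_mismatch_rejected(self):
        presets = preset_configs()
        egg = simulate_cohort(presets["control-like"].replace(n=20, seed=1))
        adult = simulate_cohort(
            presets["control-like"].replace(
                n=20, seed=1, exposure_route=ExposureRoute.topical_adult
            )
        )
        with pytest.raises(ValueError, match="exposure route"):
            score_cohort_pair(egg, adult, variant="egg")
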