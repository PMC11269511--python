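import pytest

from demotox.cohort import Cohort, CohortRecord, ExposureRoute, Sex


def make_record(rid="a", treatment="t", **kw) -> CohortRecord:
    return CohortRecord(individual_id=rid, treatment=treatment, **kw)


@pytest.fixture
def tiny_cohort() -> Cohort:
    """Two well-formed egg-route individuals: one adult female, one immature death."""
    female = CohortRecord(
        individual_id="f1",
        treatment="ctrl",
        exposure_route=ExposureRoute.topical_egg,
        hatch_age=2,
        larva_end_age=3,
        nymph_end_age=5,
        sex=Sex.female,
        death_age=12,
        daily_eggs={7: 2, 8: 1},
        viability_trials=[(3, 3)],
    )
    dead_larva = CohortRecord(
        individual_id="d1",
        treatment="ctrl",
        exposure_route=ExposureRoute.topical_egg,
        hatch_age=1,
        death_age=3,
    )
    return Cohort(treatment="ctrl", records=[female, dead_larva], n_initial=2)


@pytest.fixture
def adult_cohort() -> Cohort:
    """Adult-exposure cohort: ages count from emergence."""
    recs = [
        CohortRecord("af1", "trt", ExposureRoute.topical_adult, sex=Sex.female,
                     death_age=6, daily_eggs={2: 1, 3: 2}, viability_trials=[(3, 2)]),
        CohortRecord("am1", "trt", ExposureRoute.topical_adult, sex=Sex.male,
                     death_age=4),
        CohortRecord("am2", "trt", ExposureRoute.topical_adult, sex=Sex.male,
                     death_age=0),
    ]
    return Cohort(treatment="trt", records=recs, n_initial=3)
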