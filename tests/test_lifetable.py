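"""Life-table schedules, Euler–Lotka root finding, and derived parameters."""

import math

import numpy as np
import pytest

from demotox.cohort import Cohort, CohortRecord, ExposureRoute, Sex
from demotox.lifetable import (
    LifeSchedule,
    LifeTableError,
    NoSolutionError,
    STAGES,
    build_life_schedule,
    demographic_parameters,
    net_reproductive_rate,
    solve_euler_lotka,
    survivorship_summary,
)
from demotox.synthetic import preset_configs, simulate_cohort


def make_schedule(lx, mx) -> LifeSchedule:
    """Schedule with all survivors lumped into one stage (enough for the
    age-only computations)."""
    lx = np.asarray(lx, dtype=float)
    mx = np.asarray(mx, dtype=float)
    sxj = np.zeros((lx.size, len(STAGES)))
    sxj[:, 0] = lx
    return LifeSchedule(ages=np.arange(lx.size), sxj=sxj, lx=lx, mx=mx)


def euler_lotka_grid_oracle(lx, mx, lo=-1.0, hi=2.0, tol=1e-7) -> float:
    """Brute-force bisection over the renewal residual on a dense grid."""
    ages = np.arange(len(lx), dtype=float)
    phi = np.asarray(lx) * np.asarray(mx)

    def f(r):
        return float(np.exp(-r * (ages + 1.0)) @ phi) - 1.0

    grid = np.arange(lo, hi, 1e-3)
    vals = np.array([f(r) for r in grid])
    sign_change = np.nonzero(np.diff(np.sign(vals)) != 0)[0]
    assert sign_change.size >= 1, "oracle found no sign change in bracket"
    a, b = grid[sign_change[0]], grid[sign_change[0] + 1]
    while b - a > tol:
        m = 0.5 * (a + b)
        if f(m) > 0:
            a = m
        else:
            b = m
    return 0.5 * (a + b)


def random_schedule(rng) -> LifeSchedule:
    n_ages = rng.integers(3, 8)
    lx = np.concatenate([[1.0], np.sort(rng.uniform(0.05, 1.0, n_ages - 1))[::-1]])
    mx = rng.uniform(0.0, 3.0, n_ages)
    mx[rng.integers(0, n_ages)] += 0.5  # guarantee some reproduction
    return make_schedule(lx, mx)


class TestBuildSchedule:
    def test_lx_by_direct_count(self):
        recs = [
            CohortRecord("a", "t", death_age=1),
            CohortRecord("b", "t", hatch_age=1, larva_end_age=2, nymph_end_age=3,
                         sex=Sex.male),  # censored, last seen at age 3
        ]
        sched = build_life_schedule(Cohort("t", recs, n_initial=2))
        assert np.allclose(sched.lx, [1.0, 0.5, 0.5, 0.5])
        assert sched.censored_count == 1

    def test_mx_by_direct_count(self):
        rec = CohortRecord("f", "t", ExposureRoute.topical_adult, sex=Sex.female,
                           death_age=2, daily_eggs={1: 2})
        sched = build_life_schedule(Cohort("t", [rec], n_initial=1))
        assert np.allclose(sched.mx, [0.0, 2.0])

    def test_stage_occupancy_partition(self, tiny_cohort):
        sched = build_life_schedule(tiny_cohort)
        assert np.allclose(sched.sxj.sum(axis=1), sched.lx)
        # the female is an egg at age 0-1, larva at 2, nymph at 3-4, adult from 5
        j = dict(zip(STAGES, range(len(STAGES))))
        assert sched.sxj[0, j["egg"]] == 1.0  # both individuals are eggs
        assert sched.sxj[5, j["adult_female"]] == 0.5

    def test_simulated_cohort_invariants(self):
        cohort = simulate_cohort(preset_configs()["control-like"].replace(n=300, seed=4))
        sched = build_life_schedule(cohort)
        assert sched.lx[0] == pytest.approx(1.0)
        assert np.all(np.diff(sched.lx) <= 1e-12)
        assert np.all(sched.mx >= 0)
        assert np.all(sched.sxj >= 0)
        assert np.all(sched.sxj.sum(axis=1) <= 1 + 1e-12)

    def test_empty_cohort_rejected(self):
        with pytest.raises(LifeTableError):
            build_life_schedule(Cohort("t", [], n_initial=0))

    def test_all_dead_at_zero_rejected(self):
        recs = [CohortRecord("a", "t", death_age=0)]
        with pytest.raises(LifeTableError):
            build_life_schedule(Cohort("t", recs, n_initial=1))


class TestDemographicParameters:
    def test_r0_single_term(self):
        assert net_reproductive_rate(make_schedule([1.0], [2.0])) == 2.0

    def test_sterile_cohort_r0_zero_and_no_root(self):
        sched = make_schedule([1.0, 0.5], [0.0, 0.0])
        assert net_reproductive_rate(sched) == 0.0
        with pytest.raises(NoSolutionError):
            solve_euler_lotka(sched)

    def test_single_reproductive_age_closed_form(self):
        # all reproduction at age 0 with l0·m0 = 2: exp(-r)·2 = 1 → r = ln 2
        sched = make_schedule([1.0], [2.0])
        r = solve_euler_lotka(sched)
        assert r == pytest.approx(math.log(2), abs=1e-12)
        params = demographic_parameters(sched)
        assert params.r0 == pytest.approx(2.0)
        assert params.lam == pytest.approx(2.0)
        assert params.t_gen == pytest.approx(1.0)

    def test_replacement_rate_gives_zero_growth(self):
        sched = make_schedule([1.0], [1.0])
        assert solve_euler_lotka(sched) == pytest.approx(0.0, abs=1e-12)

    def test_lambda_is_exp_r(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            params = demographic_parameters(random_schedule(rng))
            assert params.lam == pytest.approx(math.exp(params.r), rel=1e-15)

    def test_matches_grid_scan_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            sched = random_schedule(rng)
            r = solve_euler_lotka(sched)
            r_oracle = euler_lotka_grid_oracle(sched.lx, sched.mx)
            assert abs(r - r_oracle) < 1e-6

    def test_r_increases_with_fecundity(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            sched = random_schedule(rng)
            r1 = solve_euler_lotka(sched)
            boosted = make_schedule(sched.lx, sched.mx * 1.5)
            assert solve_euler_lotka(boosted) > r1

    def test_sign_of_r_matches_r0(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            sched = random_schedule(rng)
            r = solve_euler_lotka(sched)
            r0 = net_reproductive_rate(sched)
            assert math.copysign(1, r) == math.copysign(1, r0 - 1.0) or abs(r) < 1e-9

    def test_negative_growth_for_declining_cohort(self):
        sched = make_schedule([1.0, 0.5], [0.0, 0.8])  # R0 = 0.4 < 1
        r = solve_euler_lotka(sched)
        assert r < 0

    def test_concentrated_reproduction_limit(self):
        # reproduction only at age x*: r = ln(R0)/(x*+1), T = x*+1
        x_star, r0 = 3, 5.0
        lx = [1.0, 0.9, 0.8, 0.8]
        mx = [0.0, 0.0, 0.0, r0 / 0.8]
        params = demographic_parameters(make_schedule(lx, mx))
        assert params.r == pytest.approx(math.log(r0) / (x_star + 1), rel=1e-10)
        assert params.t_gen == pytest.approx(x_star + 1, rel=1e-10)


class TestSurvivorshipSummary:
    def test_threshold_scan(self):
        sched = make_schedule([1.0, 0.6, 0.4, 0.1, 0.0], [0.0] * 5)
        assert survivorship_summary(sched) == (2, 3)

    def test_median_undefined_when_never_below_half(self):
        sched = make_schedule([1.0, 0.9, 0.8], [0.0] * 3)
        median, max_life = survivorship_summary(sched)
        assert median is None
        assert max_life == 2

    def test_control_like_median_in_expected_band(self):
        cohort = simulate_cohort(preset_configs()["control-like"].replace(n=500, seed=6))
        median, _ = survivorship_summary(build_life_schedule(cohort))
        assert 15 <= median <= 23
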