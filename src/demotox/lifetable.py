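"""Age-stage two-sex life-table computation.

Builds age-stage survival (sxj), age-specific survivorship (lx) and
age-specific fecundity (mx) schedules from an individual-level cohort and
derives the demographic parameters: net reproductive rate R0 = Σ lx·mx,
intrinsic rate of increase r solving the discrete renewal (Euler–Lotka)
equation, finite rate λ = exp(r), and mean generation time T = ln(R0)/r.

Conventions
-----------
Both sexes enter every denominator: lx counts all individuals alive at age
x out of the initial cohort, and mx averages eggs over all living
individuals at age x (not females only).  The renewal equation uses the
(x+1)-exponent form

    Σx exp(−r(x+1)) · lx · mx = 1,

i.e. ages are indexed from 0 and a newborn's first possible reproduction at
age 0 is discounted one full day.  The classic textbook form omits the +1;
with ages indexed from 1 the two coincide.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .cohort import Cohort, ExposureRoute, Sex

__all__ = [
    "STAGES",
    "LifeSchedule",
    "DemographicParams",
    "LifeTableError",
    "NoSolutionError",
    "build_life_schedule",
    "net_reproductive_rate",
    "solve_euler_lotka",
    "demographic_parameters",
    "survivorship_summary",
]

STAGES = ("egg", "larva", "nymph", "adult_female", "adult_male")
_STAGE_INDEX = {s: i for i, s in enumerate(STAGES)}

#: residual tolerance on the renewal equation at the returned root
EULER_LOTKA_TOL = 1e-10


class LifeTableError(ValueError):
    """Cohort cannot support a life-table computation."""


class NoSolutionError(LifeTableError):
    """The renewal equation has no root (R0 = 0) or root finding failed."""


@dataclass
class LifeSchedule:
    """Age-indexed schedules: sxj (age × stage occupancy probability),
    lx = Σj sxj, and mx (mean eggs per living individual)."""

    ages: np.ndarray
    sxj: np.ndarray
    lx: np.ndarray
    mx: np.ndarray
    censored_count: int = 0
    stages: tuple[str, ...] = STAGES


@dataclass
class DemographicParams:
    """R0 (offspring/individual), r and λ (per day), T (days)."""

    r0: float
    r: float
    lam: float
    t_gen: float


def _stage_of(rec, age: int) -> int:
    if rec.exposure_route is not ExposureRoute.topical_egg:
        return _STAGE_INDEX["adult_female" if rec.sex is Sex.female else "adult_male"]
    if rec.hatch_age is None or age < rec.hatch_age:
        return _STAGE_INDEX["egg"]
    if rec.larva_end_age is None or age < rec.larva_end_age:
        return _STAGE_INDEX["larva"]
    if rec.nymph_end_age is None or age < rec.nymph_end_age:
        return _STAGE_INDEX["nymph"]
    return _STAGE_INDEX["adult_female" if rec.sex is Sex.female else "adult_male"]


def build_life_schedule(cohort: Cohort) -> LifeSchedule:
    """Tally an age-stage schedule from daily census records.

    sxj[x, j] = (individuals alive in stage j at age x) / n_initial.
    Censored individuals count while under observation and drop out of both
    the numerator and the denominator of mx afterwards; their number is
    reported in ``censored_count``.
    """
    if not cohort.records or cohort.n_initial <= 0:
        raise LifeTableError("empty cohort")
    ends = []  # exclusive end of the observed-alive span
    for rec in cohort.records:
        end = rec.death_age if rec.death_age is not None else rec.last_observed_age + 1
        ends.append(end)
    max_age = max(ends) - 1
    if max_age < 0:
        raise LifeTableError("no individual observed alive at any age")
    n_ages = max_age + 1

    # stage occupancy via difference arrays: O(records + ages)
    diff = np.zeros((n_ages + 1, len(STAGES)))
    eggs_at = np.zeros(n_ages)
    alive_diff = np.zeros(n_ages + 1)
    for rec, end in zip(cohort.records, ends):
        if end <= 0:
            continue
        alive_diff[0] += 1
        alive_diff[end] -= 1
        bounds = [0]
        if rec.exposure_route is ExposureRoute.topical_egg:
            for b in (rec.hatch_age, rec.larva_end_age, rec.nymph_end_age):
                if b is None:
                    break
                bounds.append(min(b, end))
        stage_starts = bounds + [end]
        for k in range(len(stage_starts) - 1):
            start, stop = stage_starts[k], min(stage_starts[k + 1], end)
            if stop <= start:
                continue
            j = _stage_of(rec, start)
            diff[start, j] += 1
            diff[stop, j] -= 1
        for age, k in rec.daily_eggs.items():
            if 0 <= age < n_ages:
                eggs_at[age] += k

    counts = np.cumsum(diff[:-1], axis=0)
    alive_n = np.cumsum(alive_diff[:-1])
    sxj = counts / cohort.n_initial
    lx = alive_n / cohort.n_initial
    with np.errstate(invalid="ignore", divide="ignore"):
        mx = np.where(alive_n > 0, eggs_at / np.maximum(alive_n, 1), 0.0)
    return LifeSchedule(
        ages=np.arange(n_ages),
        sxj=sxj,
        lx=lx,
        mx=mx,
        censored_count=cohort.censored_count,
    )


def net_reproductive_rate(schedule: LifeSchedule) -> float:
    """R0 = Σx lx·mx — expected lifetime offspring per initial individual."""
    return float(schedule.lx @ schedule.mx)


def _renewal_residual(r: float, ages: np.ndarray, phi: np.ndarray) -> float:
    return float(np.exp(-r * (ages + 1.0)) @ phi) - 1.0


def solve_euler_lotka(schedule: LifeSchedule) -> float:
    """Solve Σx exp(−r(x+1))·lx·mx = 1 for the intrinsic rate of increase.

    The left side is strictly decreasing in r, so the real root is unique.
    A bracketing interval (default [−1, 2], widened geometrically when
    needed) is solved by Brent's method and the residual is verified
    against ``EULER_LOTKA_TOL``.  Negative r (declining cohorts, R0 < 1)
    is a legitimate outcome.
    """
    phi = schedule.lx * schedule.mx
    keep = phi > 0
    if not np.any(keep):
        raise NoSolutionError("R0 = 0: no reproduction, renewal equation has no root")
    ages = schedule.ages[keep].astype(float)
    phi = phi[keep]

    lo, hi = -1.0, 2.0
    for _ in range(200):
        if _renewal_residual(lo, ages, phi) > 0:
            break
        lo *= 2.0
    else:
        raise NoSolutionError(f"could not bracket the root from below (lo={lo})")
    for _ in range(200):
        if _renewal_residual(hi, ages, phi) < 0:
            break
        hi *= 2.0
    else:
        raise NoSolutionError(f"could not bracket the root from above (hi={hi})")

    r = brentq(
        _renewal_residual, lo, hi, args=(ages, phi), xtol=1e-14, rtol=8.9e-16,
        maxiter=200,
    )
    resid = _renewal_residual(r, ages, phi)
    if abs(resid) > EULER_LOTKA_TOL:
        raise NoSolutionError(
            f"renewal residual {resid:.3e} at r={r:.8f} exceeds tolerance "
            f"(bracket [{lo}, {hi}])"
        )
    return float(r)


def demographic_parameters(schedule: LifeSchedule) -> DemographicParams:
    """Bundle R0, r, λ = exp(r) and mean generation time T.

    T = ln(R0)/r, the time for the population to grow R0-fold at rate r;
    as r → 0 this tends to the fecundity-weighted mean reproductive age
    Σ (x+1)·lx·mx / R0 (with the same (x+1) day-indexing as the renewal
    equation), which is used when |r| is numerically zero.
    """
    r0 = net_reproductive_rate(schedule)
    r = solve_euler_lotka(schedule)
    lam = math.exp(r)
    if abs(r) > 1e-9:
        t_gen = math.log(r0) / r
    else:
        phi = schedule.lx * schedule.mx
        t_gen = float((schedule.ages + 1.0) @ phi) / r0
    return DemographicParams(r0=r0, r=r, lam=lam, t_gen=t_gen)


def survivorship_summary(schedule: LifeSchedule) -> tuple[int | None, int]:
    """(median survival age, max lifespan).

    Median = smallest age with lx < 0.5 (None when survivorship never drops
    below one half, e.g. heavy censoring); max lifespan = last age with
    lx > 0.
    """
    below = np.nonzero(schedule.lx < 0.5)[0]
    median = int(below[0]) if below.size else None
    alive = np.nonzero(schedule.lx > 0)[0]
    max_lifespan = int(alive[-1]) if alive.size else 0
    return median, max_lifespan
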