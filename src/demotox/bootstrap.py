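"""Bootstrap standard errors and paired tests for cohort-level statistics.

The resampling unit is the individual: each replicate redraws ``n_initial``
whole life-history records with replacement and recomputes the statistic
from scratch.  Replicates on which the statistic is undefined (e.g. no
surviving females for a longevity mean, or R0 = 0 for the intrinsic rate)
are dropped and counted, mirroring the study-level practice of estimating
demographic parameters only where enough of the cohort survives.

Default B is 100,000 resamples; analyses that only need indicative
uncertainty (test suites, smoke runs) scale B down to 1,000–2,000.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .cohort import Cohort, CohortRecord, Sex
from .lifetable import (
    LifeTableError,
    build_life_schedule,
    demographic_parameters,
    net_reproductive_rate,
)

__all__ = [
    "STATISTICS",
    "BootstrapEstimate",
    "PairedTestResult",
    "StatisticUndefined",
    "DegenerateEstimateError",
    "resolve_statistic",
    "bootstrap_estimate",
    "paired_bootstrap_test",
]

DEFAULT_B = 100_000


class StatisticUndefined(ValueError):
    """The statistic has no value on this (re)sampled cohort."""


class DegenerateEstimateError(ValueError):
    """The statistic was undefined on more than half of the replicates."""


def _require(cond: bool, why: str) -> None:
    if not cond:
        raise StatisticUndefined(why)


def _stat_r0(c: Cohort) -> float:
    try:
        return net_reproductive_rate(build_life_schedule(c))
    except LifeTableError as exc:
        raise StatisticUndefined(str(exc)) from exc


def _demo(c: Cohort):
    try:
        sched = build_life_schedule(c)
        return demographic_parameters(sched)
    except LifeTableError as exc:
        raise StatisticUndefined(str(exc)) from exc


def _adult_females(c: Cohort) -> list[CohortRecord]:
    return [
        r for r in c.records
        if r.sex is Sex.female and r.reached_adulthood and r.death_age is not None
    ]


def _adult_males(c: Cohort) -> list[CohortRecord]:
    return [
        r for r in c.records
        if r.sex is Sex.male and r.reached_adulthood and r.death_age is not None
    ]


def _stat_mean_female_longevity(c: Cohort) -> float:
    fem = _adult_females(c)
    _require(len(fem) > 0, "no uncensored adult females")
    return float(np.mean([r.adult_longevity for r in fem]))


def _stat_mean_male_longevity(c: Cohort) -> float:
    males = _adult_males(c)
    _require(len(males) > 0, "no uncensored adult males")
    return float(np.mean([r.adult_longevity for r in males]))


def _stat_total_fecundity(c: Cohort) -> float:
    fem = [r for r in c.records if r.sex is Sex.female and r.reached_adulthood]
    _require(len(fem) > 0, "no adult females")
    return float(np.mean([r.total_eggs for r in fem]))


def _stat_viability_pct(c: Cohort) -> float:
    tested = hatched = 0
    for r in c.records:
        for t, h in r.viability_trials:
            tested += t
            hatched += h
    _require(tested > 0, "no viability trials")
    return 100.0 * hatched / tested


def _stat_preadult_survival(c: Cohort) -> float:
    return sum(r.reached_adulthood for r in c.records) / c.n_initial


def _stat_preadult_duration(c: Cohort) -> float:
    adults = [r for r in c.records if r.nymph_end_age is not None]
    _require(len(adults) > 0, "no individuals completed development")
    return float(np.mean([r.nymph_end_age for r in adults]))


STATISTICS: dict[str, Callable[[Cohort], float]] = {
    "R0": _stat_r0,
    "r": lambda c: _demo(c).r,
    "lambda": lambda c: _demo(c).lam,
    "T": lambda c: _demo(c).t_gen,
    "mean_female_longevity": _stat_mean_female_longevity,
    "mean_male_longevity": _stat_mean_male_longevity,
    "total_fecundity": _stat_total_fecundity,
    "viability_pct": _stat_viability_pct,
    "preadult_survival": _stat_preadult_survival,
    "preadult_duration": _stat_preadult_duration,
}


def resolve_statistic(statistic) -> tuple[str, Callable[[Cohort], float]]:
    if callable(statistic):
        return getattr(statistic, "__name__", "statistic"), statistic
    try:
        return statistic, STATISTICS[statistic]
    except KeyError:
        raise KeyError(
            f"unknown statistic {statistic!r}; known: {sorted(STATISTICS)}"
        ) from None


@dataclass
class BootstrapEstimate:
    statistic_name: str
    point: float
    se: float
    ci95: tuple[float, float]
    B: int
    seed: int
    n_failed: int


@dataclass
class PairedTestResult:
    statistic_name: str
    diff_point: float
    diff_ci95: tuple[float, float]
    p_value: float
    B: int
    seed: int
    n_failed: int


def _resample(cohort: Cohort, idx: np.ndarray) -> Cohort:
    recs = cohort.records
    return Cohort(
        treatment=cohort.treatment,
        records=[recs[i] for i in idx],
        n_initial=cohort.n_initial,
    )


def bootstrap_estimate(
    cohort: Cohort,
    statistic,
    B: int = DEFAULT_B,
    seed: int = 0,
) -> BootstrapEstimate:
    """Percentile bootstrap over whole individuals; deterministic given seed.

    The standard error is the (ddof=1) standard deviation of the successful
    replicate values and ci95 their 2.5/97.5 percentiles.  More than 50% of
    undefined replicates raises :class:`DegenerateEstimateError`.
    """
    if B < 100:
        raise ValueError("B must be >= 100")
    name, fn = resolve_statistic(statistic)
    point = fn(cohort)
    n = len(cohort.records)
    rng = np.random.default_rng(seed)
    values = np.empty(B)
    n_ok = 0
    n_failed = 0
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        try:
            values[n_ok] = fn(_resample(cohort, idx))
            n_ok += 1
        except StatisticUndefined:
            n_failed += 1
    if n_failed > B // 2:
        raise DegenerateEstimateError(
            f"statistic {name!r} undefined on {n_failed}/{B} replicates"
        )
    vals = values[:n_ok]
    se = float(np.std(vals, ddof=1)) if n_ok > 1 else 0.0
    lo, hi = np.percentile(vals, [2.5, 97.5])
    return BootstrapEstimate(
        statistic_name=name,
        point=float(point),
        se=se,
        ci95=(float(lo), float(hi)),
        B=B,
        seed=seed,
        n_failed=n_failed,
    )


def paired_bootstrap_test(
    cohort_a: Cohort,
    cohort_b: Cohort,
    statistic,
    B: int = DEFAULT_B,
    seed: int = 0,
) -> PairedTestResult:
    """Two-sided percentile bootstrap test of statistic(A) − statistic(B).

    Each replicate independently resamples both cohorts; the two-sided
    p-value is 2·min(P(diff ≤ 0), P(diff ≥ 0)), floored at 1/B and capped
    at 1, so that 0 lies outside the 95% percentile interval of the
    differences iff p < 0.05 (up to the 1/B resolution).
    """
    if B < 100:
        raise ValueError("B must be >= 100")
    name, fn = resolve_statistic(statistic)
    diff_point = fn(cohort_a) - fn(cohort_b)
    na, nb = len(cohort_a.records), len(cohort_b.records)
    rng = np.random.default_rng(seed)
    diffs = np.empty(B)
    n_ok = 0
    n_failed = 0
    for _ in range(B):
        ia = rng.integers(0, na, size=na)
        ib = rng.integers(0, nb, size=nb)
        try:
            va = fn(_resample(cohort_a, ia))
            vb = fn(_resample(cohort_b, ib))
            diffs[n_ok] = va - vb
            n_ok += 1
        except StatisticUndefined:
            n_failed += 1
    if n_failed > B // 2:
        raise DegenerateEstimateError(
            f"statistic {name!r} undefined on {n_failed}/{B} paired replicates"
        )
    d = diffs[:n_ok]
    frac_le = float(np.mean(d <= 0))
    frac_ge = float(np.mean(d >= 0))
    p = max(1.0 / B, 2.0 * min(frac_le, frac_ge))
    p = min(1.0, p)
    lo, hi = np.percentile(d, [2.5, 97.5])
    return PairedTestResult(
        statistic_name=name,
        diff_point=float(diff_point),
        diff_ci95=(float(lo), float(hi)),
        p_value=p,
        B=B,
        seed=seed,
        n_failed=n_failed,
    )
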