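"""Corrected mortality, reduction coefficient Ex, and IOBC classification.

The reduction coefficient condenses a pesticide's lethal and sublethal
side effects on a natural enemy into one percentage,

    Ex = 100 − (100 − Mc) · R1 · R2 (· R3),

where Mc is control-corrected mortality (Henderson–Tilton), R1 the
treated/control ratio of eggs laid per female, R2 the ratio of egg
viability, and R3 (egg-stage assessments only) the ratio of female
longevity.  Ex is banded into the IOBC toxicity classes I–IV; residue-age
series of extended-laboratory assessments are in turn banded into the
IOBC persistence classes A–D by the time the deposit takes to become
harmless (class I).
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field

from .cohort import Cohort, ExposureRoute, Sex

__all__ = [
    "IOBCClass",
    "Scheme",
    "PersistenceClass",
    "MortalityCounts",
    "ReductionInputs",
    "ToxicityAssessment",
    "ResidueSeries",
    "PersistenceResult",
    "UndefinedCorrectionError",
    "UndefinedRatioError",
    "corrected_mortality",
    "corrected_mortality_pct",
    "reduction_coefficient",
    "classify_iobc",
    "assess_persistence",
    "score_cohort_pair",
]


class IOBCClass(str, enum.Enum):
    I = "I"      # harmless
    II = "II"    # slightly harmful
    III = "III"  # moderately harmful
    IV = "IV"    # harmful


class Scheme(str, enum.Enum):
    lab = "lab"                    # topical laboratory test bands
    extended_lab = "extended_lab"  # extended-laboratory (residue) bands


class PersistenceClass(str, enum.Enum):
    A = "A"  # short-lived: harmless in < 5 days
    B = "B"  # slightly persistent: 5-15 days
    C = "C"  # moderately persistent: 16-30 days
    D = "D"  # highly persistent: > 30 days


class UndefinedCorrectionError(ZeroDivisionError):
    """Control mortality is total: corrected mortality is undefined."""


class UndefinedRatioError(ZeroDivisionError):
    """A control denominator (fecundity/viability/longevity) is zero."""


@dataclass(frozen=True)
class MortalityCounts:
    """Live counts before/after exposure in the control and treated arms."""

    control_before: int
    control_after: int
    treated_before: int
    treated_after: int

    def __post_init__(self):
        if self.control_before <= 0 or self.treated_before <= 0:
            raise ValueError("before-counts must be > 0")
        if self.control_after > self.control_before:
            raise ValueError("control_after exceeds control_before")
        if self.treated_after > self.treated_before:
            raise ValueError("treated_after exceeds treated_before")
        if min(self.control_after, self.treated_after) < 0:
            raise ValueError("counts must be non-negative")


def corrected_mortality(counts: MortalityCounts) -> float:
    """Henderson–Tilton corrected mortality, %.

    Mc = 100·(1 − (Co_before · T_after) / (Co_after · T_before)), clamped
    to [0, 100].  With equal before-counts this reduces to the
    Abbott/Schneider–Orelli correction on survival fractions.
    """
    if counts.control_after == 0:
        raise UndefinedCorrectionError(
            "total control mortality: Henderson-Tilton correction undefined"
        )
    mc = 100.0 * (
        1.0
        - (counts.control_before * counts.treated_after)
        / (counts.control_after * counts.treated_before)
    )
    return min(100.0, max(0.0, mc))


def corrected_mortality_pct(control_mortality_pct: float,
                            treated_mortality_pct: float) -> float:
    """Abbott-form correction from observed mortality percentages
    (Henderson–Tilton with equal before-counts)."""
    if control_mortality_pct >= 100.0:
        raise UndefinedCorrectionError("total control mortality")
    mc = 100.0 * (
        1.0 - (100.0 - treated_mortality_pct) / (100.0 - control_mortality_pct)
    )
    return min(100.0, max(0.0, mc))


@dataclass(frozen=True)
class ReductionInputs:
    """Summaries feeding Ex; control denominators must be positive."""

    mc: float
    fecundity_t: float
    fecundity_c: float
    viability_t: float
    viability_c: float
    longevity_t: float | None = None
    longevity_c: float | None = None

    def __post_init__(self):
        if not 0.0 <= self.mc <= 100.0:
            raise ValueError(f"mc must lie in [0, 100], got {self.mc}")
        if self.fecundity_c <= 0 or self.viability_c <= 0:
            raise UndefinedRatioError("control fecundity/viability must be > 0")
        if self.longevity_c is not None and self.longevity_c <= 0:
            raise UndefinedRatioError("control longevity must be > 0")


def reduction_coefficient(inputs: ReductionInputs,
                          include_longevity: bool = False) -> float:
    """Ex = 100 − (100 − Mc)·R1·R2(·R3), clamped to [0, 100].

    Ratios are used as computed and may exceed 1 (a treatment can raise a
    trait above the control); the unclamped value is available from
    :func:`reduction_coefficient_raw`.
    """
    return min(100.0, max(0.0, reduction_coefficient_raw(inputs, include_longevity)))


def reduction_coefficient_raw(inputs: ReductionInputs,
                              include_longevity: bool = False) -> float:
    r1 = inputs.fecundity_t / inputs.fecundity_c
    r2 = inputs.viability_t / inputs.viability_c
    ex = 100.0 - (100.0 - inputs.mc) * r1 * r2
    if include_longevity:
        if inputs.longevity_t is None or inputs.longevity_c is None:
            raise ValueError("longevities required when include_longevity=True")
        ex = 100.0 - (100.0 - inputs.mc) * r1 * r2 * (
            inputs.longevity_t / inputs.longevity_c
        )
    return ex


def classify_iobc(ex: float, scheme: Scheme = Scheme.lab) -> IOBCClass:
    """Band a (clamped) Ex value into IOBC toxicity classes.

    Laboratory scheme: I < 30 ≤ II < 80 ≤ III ≤ 99 < IV.
    Extended-laboratory scheme: I < 25 ≤ II ≤ 50 < III ≤ 75 < IV.
    The published band edges leave small gaps (79–80, 99–100 and 50–51);
    these half-open intervals close them consistently with every published
    (Ex, class) pair.
    """
    if not 0.0 <= ex <= 100.0:
        raise ValueError(f"ex must be clamped to [0, 100], got {ex}")
    if scheme is Scheme.lab:
        if ex < 30.0:
            return IOBCClass.I
        if ex < 80.0:
            return IOBCClass.II
        if ex <= 99.0:
            return IOBCClass.III
        return IOBCClass.IV
    if ex < 25.0:
        return IOBCClass.I
    if ex <= 50.0:
        return IOBCClass.II
    if ex <= 75.0:
        return IOBCClass.III
    return IOBCClass.IV


@dataclass
class ToxicityAssessment:
    ex: float                      # clamped to [0, 100]
    scheme: Scheme
    iobc_class: IOBCClass
    ex_raw: float | None = None    # unclamped value, may fall outside [0, 100]
    mc: float | None = None
    r1: float | None = None
    r2: float | None = None
    r3: float | None = None


def assess(inputs: ReductionInputs, scheme: Scheme,
           include_longevity: bool = False) -> ToxicityAssessment:
    """Convenience: Ex plus its IOBC class under the given scheme."""
    raw = reduction_coefficient_raw(inputs, include_longevity)
    ex = min(100.0, max(0.0, raw))
    r3 = None
    if include_longevity and inputs.longevity_c:
        r3 = inputs.longevity_t / inputs.longevity_c
    return ToxicityAssessment(
        ex=ex,
        scheme=scheme,
        iobc_class=classify_iobc(ex, scheme),
        ex_raw=raw,
        mc=inputs.mc,
        r1=inputs.fecundity_t / inputs.fecundity_c,
        r2=inputs.viability_t / inputs.viability_c,
        r3=r3,
    )


@dataclass
class ResidueSeries:
    """Extended-laboratory assessments keyed by residue age (days after
    application), strictly increasing."""

    treatment: str
    assessments: dict[int, ToxicityAssessment] = field(default_factory=dict)

    def __post_init__(self):
        if not self.assessments:
            raise ValueError("ResidueSeries needs at least one time point")
        days = list(self.assessments)
        if days != sorted(set(days)) or min(days) <= 0:
            raise ValueError("days_after_application must be positive and increasing")


@dataclass
class PersistenceResult:
    treatment: str
    persistence_class: PersistenceClass
    days_to_harmless: int | None
    warnings: list[str] = field(default_factory=list)


def assess_persistence(series: ResidueSeries) -> PersistenceResult:
    """Band a residue-age series into IOBC persistence classes A–D.

    days_to_harmless is the earliest assessed residue age classified
    harmless (I) with no later harmful assessment; a non-monotone recovery
    (I followed by a non-I) falls back to the day after the last harmful
    assessment and emits a warning.  Classes: A < 5 ≤ B ≤ 15 < C ≤ 30 < D,
    with D also covering deposits never observed harmless.
    """
    days = sorted(series.assessments)
    classes = {d: series.assessments[d].iobc_class for d in days}
    harmful_days = [d for d in days if classes[d] is not IOBCClass.I]
    notes: list[str] = []
    if not harmful_days:
        days_to_harmless: int | None = days[0]
    else:
        last_harmful = harmful_days[-1]
        later_harmless = [d for d in days if d > last_harmful]
        early_harmless = [d for d in days if d < last_harmful and classes[d] is IOBCClass.I]
        if early_harmless:
            msg = (
                f"{series.treatment}: non-monotone recovery (harmless at "
                f"{early_harmless} but harmful again at day {last_harmful}); "
                "using the last transition"
            )
            notes.append(msg)
            warnings.warn(msg)
        days_to_harmless = later_harmless[0] if later_harmless else None
    if days_to_harmless is None:
        cls = PersistenceClass.D
    elif days_to_harmless < 5:
        cls = PersistenceClass.A
    elif days_to_harmless <= 15:
        cls = PersistenceClass.B
    elif days_to_harmless <= 30:
        cls = PersistenceClass.C
    else:
        cls = PersistenceClass.D
    return PersistenceResult(
        treatment=series.treatment,
        persistence_class=cls,
        days_to_harmless=days_to_harmless,
        warnings=notes,
    )


# ---------------------------------------------------------------------------
# Cohort-level scoring
# ---------------------------------------------------------------------------

def _cohort_summaries(cohort: Cohort):
    """(survivors, mean eggs/female, pooled viability %, mean female longevity)."""
    fem = [r for r in cohort.records if r.sex is Sex.female and r.reached_adulthood]
    fec = sum(r.total_eggs for r in fem) / len(fem) if fem else 0.0
    tested = sum(t for r in cohort.records for t, _ in r.viability_trials)
    hatched = sum(h for r in cohort.records for _, h in r.viability_trials)
    viab = 100.0 * hatched / tested if tested else 0.0
    lons = [r.adult_longevity for r in fem if r.adult_longevity is not None]
    lon = sum(lons) / len(lons) if lons else 0.0
    return fec, viab, lon


def _survivors(cohort: Cohort, variant: str) -> int:
    if variant == "egg":
        return sum(r.nymph_end_age is not None for r in cohort.records)
    # adult variant: survived the first 24 h after spraying
    return sum(r.death_age is None or r.death_age >= 1 for r in cohort.records)


def score_cohort_pair(control: Cohort, treated: Cohort,
                      variant: str = "egg") -> ToxicityAssessment:
    """Laboratory-scheme assessment of a treated cohort against its control.

    The egg variant corrects pre-adult mortality and includes the female
    longevity ratio R3; the adult variant corrects 24-h adult mortality and
    uses the two-factor form (no R3), matching how the two exposure
    experiments are scored.
    """
    if variant not in ("egg", "adult"):
        raise ValueError(f"variant must be 'egg' or 'adult', got {variant!r}")
    if control.exposure_route is not treated.exposure_route:
        raise ValueError("control and treated cohorts use different exposure routes")
    counts = MortalityCounts(
        control_before=control.n_initial,
        control_after=_survivors(control, variant),
        treated_before=treated.n_initial,
        treated_after=_survivors(treated, variant),
    )
    mc = corrected_mortality(counts)
    fec_c, viab_c, lon_c = _cohort_summaries(control)
    fec_t, viab_t, lon_t = _cohort_summaries(treated)
    if fec_c <= 0 or viab_c <= 0 or (variant == "egg" and lon_c <= 0):
        raise UndefinedRatioError(
            "control cohort has no reproducing females; ratios undefined"
        )
    if mc >= 100.0 or (fec_t == 0 and viab_t == 0):
        # no reproducing survivors in the treated arm: total effect
        return ToxicityAssessment(
            ex=100.0, scheme=Scheme.lab, iobc_class=IOBCClass.IV,
            ex_raw=100.0, mc=mc, r1=0.0, r2=0.0,
            r3=0.0 if variant == "egg" else None,
        )
    inputs = ReductionInputs(
        mc=mc,
        fecundity_t=fec_t,
        fecundity_c=fec_c,
        viability_t=viab_t if viab_t > 0 else viab_c,  # no trials: neutral ratio
        viability_c=viab_c,
        longevity_t=lon_t if variant == "egg" else None,
        longevity_c=lon_c if variant == "egg" else None,
    )
    return assess(inputs, Scheme.lab, include_longevity=(variant == "egg"))
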