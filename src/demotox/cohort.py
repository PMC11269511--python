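"""Individual life-history cohorts and residue-assay summaries.

A cohort is one treatment arm of a life-table response experiment: a fixed
number of individuals (eggs or newly emerged adults) followed daily from the
start of exposure until death.  Each :class:`CohortRecord` stores the integer
census ages at which the individual completed its immature stages (egg,
larva, nymph), its sex once adult, its death age, its daily egg counts, and
the egg-viability trials run on its offspring.

Age conventions
---------------
Age 0 is the day of oviposition for egg-exposure cohorts and the day of
adult emergence for adult-exposure cohorts.  All ages are integer days
(daily census).  An individual found dead at a census is recorded with
``death_age`` equal to that census day and is considered alive at every age
strictly below it; one found dead on a transition day is assigned to the
earlier stage (the later stage boundary stays unset).  ``death_age = None``
means alive at the last census (right-censored).  Eggs that never hatch are
recorded dead at age 4 with ``hatch_age = None``.
"""

from __future__ import annotations

import csv
import enum
import io
from dataclasses import dataclass, field
from typing import Iterable, TextIO

__all__ = [
    "ExposureRoute",
    "Sex",
    "CohortRecord",
    "Cohort",
    "ResidueAssayRow",
    "Violation",
    "CohortParseError",
    "validate_cohort",
    "read_cohort_csv",
    "write_cohort_csv",
    "read_residue_csv",
    "write_residue_csv",
]

FORMAT_VERSION = "demotox-cohort v1"


class ExposureRoute(str, enum.Enum):
    topical_egg = "topical_egg"
    topical_adult = "topical_adult"
    residual = "residual"


class Sex(str, enum.Enum):
    female = "female"
    male = "male"
    unknown = "unknown"


class CohortParseError(ValueError):
    """Raised on malformed cohort/residue CSV input; carries the line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


@dataclass
class CohortRecord:
    """Full life history of one individual within a treatment cohort."""

    individual_id: str
    treatment: str
    exposure_route: ExposureRoute = ExposureRoute.topical_egg
    hatch_age: int | None = None
    larva_end_age: int | None = None
    nymph_end_age: int | None = None
    sex: Sex = Sex.unknown
    death_age: int | None = None
    daily_eggs: dict[int, int] = field(default_factory=dict)
    viability_trials: list[tuple[int, int]] = field(default_factory=list)

    @property
    def is_censored(self) -> bool:
        return self.death_age is None

    @property
    def reached_adulthood(self) -> bool:
        if self.exposure_route is ExposureRoute.topical_egg:
            return self.nymph_end_age is not None
        # adult-exposure individuals start the experiment as adults
        return True

    @property
    def adult_emergence_age(self) -> int | None:
        """Age at adult emergence on this cohort's clock (0 for adult routes)."""
        if self.exposure_route is ExposureRoute.topical_egg:
            return self.nymph_end_age
        return 0

    @property
    def adult_longevity(self) -> int | None:
        """Days lived as an adult; None if immature death or censored."""
        if not self.reached_adulthood or self.death_age is None:
            return None
        return self.death_age - self.adult_emergence_age

    @property
    def total_eggs(self) -> int:
        return sum(self.daily_eggs.values())

    @property
    def last_observed_age(self) -> int:
        """Latest age at which the individual was observed alive."""
        if self.death_age is not None:
            return max(self.death_age - 1, 0)
        candidates = [0]
        for a in (self.hatch_age, self.larva_end_age, self.nymph_end_age):
            if a is not None:
                candidates.append(a)
        if self.daily_eggs:
            candidates.append(max(self.daily_eggs))
        return max(candidates)

    def alive_at(self, age: int) -> bool:
        if self.death_age is not None:
            return age < self.death_age
        return age <= self.last_observed_age


@dataclass
class Cohort:
    """One treatment arm: every initial individual has a record."""

    treatment: str
    records: list[CohortRecord]
    n_initial: int

    def __post_init__(self):
        if self.n_initial < 0:
            raise ValueError("n_initial must be non-negative")

    @property
    def exposure_route(self) -> ExposureRoute:
        if not self.records:
            return ExposureRoute.topical_egg
        return self.records[0].exposure_route

    @property
    def censored_count(self) -> int:
        return sum(r.is_censored for r in self.records)


@dataclass
class ResidueAssayRow:
    """Summary of one residue-age bioassay time point for one treatment."""

    treatment: str
    days_after_application: int
    mortality_pct: float
    is_corrected: bool
    fecundity_per_female: float
    viability_pct: float

    def __post_init__(self):
        if self.days_after_application <= 0:
            raise ValueError("days_after_application must be > 0")
        for name in ("mortality_pct", "viability_pct"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name} must lie in [0, 100], got {v}")
        if self.fecundity_per_female < 0:
            raise ValueError("fecundity_per_female must be >= 0")


@dataclass(frozen=True)
class Violation:
    """One broken invariant, naming the offending individual and rule."""

    individual_id: str | None
    rule: str
    detail: str

    def __str__(self) -> str:
        who = self.individual_id or "<cohort>"
        return f"{who}: {self.rule}: {self.detail}"


def validate_cohort(cohort: Cohort) -> list[Violation]:
    """Check every record invariant; returns [] iff the cohort is well formed.

    Violations are returned rather than raised so that a file-level report
    can list every problem at once.
    """
    out: list[Violation] = []

    if cohort.n_initial != len(cohort.records):
        out.append(
            Violation(
                None,
                "n_initial",
                f"n_initial={cohort.n_initial} but {len(cohort.records)} records; "
                "every initial individual must have a record",
            )
        )
    seen_ids: set[str] = set()
    for rec in cohort.records:
        rid = rec.individual_id
        if rid in seen_ids:
            out.append(Violation(rid, "unique_id", "duplicate individual_id"))
        seen_ids.add(rid)
        if rec.treatment != cohort.treatment:
            out.append(
                Violation(
                    rid,
                    "treatment",
                    f"record treatment {rec.treatment!r} != cohort {cohort.treatment!r}",
                )
            )
        # ordering chain wherever defined
        chain = [
            ("hatch_age", rec.hatch_age),
            ("larva_end_age", rec.larva_end_age),
            ("nymph_end_age", rec.nymph_end_age),
            ("death_age", rec.death_age),
        ]
        defined = [(n, a) for n, a in chain if a is not None]
        for n, a in defined:
            if a < 0:
                out.append(Violation(rid, "age_domain", f"{n}={a} is negative"))
        for (n1, a1), (n2, a2) in zip(defined, defined[1:]):
            if a1 > a2:
                out.append(
                    Violation(rid, "stage_order", f"{n1}={a1} > {n2}={a2}")
                )
        # later stage boundary set while an earlier one is missing
        names = [n for n, a in chain[:3] if a is not None]
        if rec.exposure_route is ExposureRoute.topical_egg:
            expected_prefix = ["hatch_age", "larva_end_age", "nymph_end_age"][: len(names)]
            if names != expected_prefix:
                out.append(
                    Violation(
                        rid,
                        "stage_order",
                        f"stage boundaries {names} skip an earlier stage",
                    )
                )
        if rec.daily_eggs:
            if rec.sex is not Sex.female:
                out.append(
                    Violation(rid, "sex_fecundity", "daily_eggs set for a non-female")
                )
            if not rec.reached_adulthood:
                out.append(
                    Violation(rid, "immature_fecundity", "daily_eggs set for an immature")
                )
            emergence = rec.adult_emergence_age
            if emergence is not None:
                bad = [a for a in rec.daily_eggs if a < emergence]
                if bad:
                    out.append(
                        Violation(
                            rid,
                            "egg_age",
                            f"daily_eggs at ages {sorted(bad)} before adult "
                            f"emergence age {emergence}",
                        )
                    )
            for a, k in rec.daily_eggs.items():
                if a < 0 or k < 0:
                    out.append(
                        Violation(rid, "egg_domain", f"daily_eggs[{a}]={k} out of domain")
                    )
        if rec.sex is Sex.unknown and rec.reached_adulthood:
            out.append(
                Violation(rid, "sex_unknown", "sex unknown for an adult individual")
            )
        for tested, hatched in rec.viability_trials:
            if tested < 0 or hatched < 0 or hatched > tested:
                out.append(
                    Violation(
                        rid,
                        "viability_trial",
                        f"trial ({tested}, {hatched}) violates 0 <= hatched <= tested",
                    )
                )
    return out


# ---------------------------------------------------------------------------
# CSV I/O — long event format, one row per individual-day event.
# ---------------------------------------------------------------------------

_CSV_HEADER = ["individual_id", "treatment", "event_type", "age_day", "value"]
_UNIQUE_EVENTS = {"enroll", "hatch", "larva_end", "nymph_end", "sex", "death"}


def write_cohort_csv(cohort: Cohort, path_or_buf: str | TextIO) -> None:
    """Write a cohort in the long event CSV format (UTF-8, '.' decimal).

    Every individual gets an ``enroll`` row (age 0, value = exposure route),
    so individuals with no further events round-trip intact.
    """
    own = isinstance(path_or_buf, str)
    fh = open(path_or_buf, "w", encoding="utf-8", newline="") if own else path_or_buf
    try:
        fh.write(f"# {FORMAT_VERSION}\n")
        fh.write(f"# treatment={cohort.treatment}\n")
        fh.write(f"# n_initial={cohort.n_initial}\n")
        w = csv.writer(fh)
        w.writerow(_CSV_HEADER)
        for rec in cohort.records:
            rid, tr = rec.individual_id, rec.treatment
            w.writerow([rid, tr, "enroll", 0, rec.exposure_route.value])
            for ev, age in [
                ("hatch", rec.hatch_age),
                ("larva_end", rec.larva_end_age),
                ("nymph_end", rec.nymph_end_age),
            ]:
                if age is not None:
                    w.writerow([rid, tr, ev, age, ""])
            if rec.sex is not Sex.unknown:
                w.writerow([rid, tr, "sex", 0, rec.sex.value])
            if rec.death_age is not None:
                w.writerow([rid, tr, "death", rec.death_age, ""])
            for age in sorted(rec.daily_eggs):
                w.writerow([rid, tr, "eggs", age, rec.daily_eggs[age]])
            for i, (tested, hatched) in enumerate(rec.viability_trials):
                w.writerow([rid, tr, "viability", i, f"{tested}:{hatched}"])
    finally:
        if own:
            fh.close()


def read_cohort_csv(path_or_buf: str | TextIO) -> Cohort:
    """Read a cohort from the long event CSV format.

    Raises :class:`CohortParseError` with a line number on malformed rows,
    negative ages, or duplicate events for the same individual/age.
    """
    own = isinstance(path_or_buf, str)
    fh = open(path_or_buf, "r", encoding="utf-8", newline="") if own else path_or_buf
    try:
        return _parse_cohort(fh)
    finally:
        if own:
            fh.close()


def _parse_cohort(fh: TextIO) -> Cohort:
    treatment: str | None = None
    n_initial: int | None = None
    lines = fh.read().splitlines()
    body_start = 0
    for i, line in enumerate(lines):
        if not line.startswith("#"):
            body_start = i
            break
        meta = line.lstrip("# ").strip()
        if meta.startswith("treatment="):
            treatment = meta.split("=", 1)[1]
        elif meta.startswith("n_initial="):
            try:
                n_initial = int(meta.split("=", 1)[1])
            except ValueError:
                raise CohortParseError("n_initial header is not an integer", i + 1)
    else:
        body_start = len(lines)

    body = lines[body_start:]
    if not body:
        raise CohortParseError("missing header row", body_start + 1)
    reader = csv.reader(io.StringIO("\n".join(body)))
    header = next(reader)
    if header != _CSV_HEADER:
        raise CohortParseError(
            f"unexpected header {header!r}, want {_CSV_HEADER!r}", body_start + 1
        )

    order: list[str] = []
    records: dict[str, CohortRecord] = {}
    seen_events: set[tuple[str, str, int]] = set()
    for rownum, row in enumerate(reader, start=body_start + 2):
        if not row:
            continue
        if len(row) != 5:
            raise CohortParseError(f"expected 5 columns, got {len(row)}", rownum)
        rid, tr, ev, age_s, value = row
        try:
            age = int(age_s)
        except ValueError:
            raise CohortParseError(f"age_day {age_s!r} is not an integer", rownum)
        if age < 0:
            raise CohortParseError(f"age_day {age} is negative", rownum)
        if treatment is None:
            treatment = tr
        if rid not in records:
            order.append(rid)
            records[rid] = CohortRecord(individual_id=rid, treatment=tr)
        rec = records[rid]
        key = (rid, ev, age if ev in ("eggs", "viability") else -1)
        if key in seen_events and ev != "viability":
            raise CohortParseError(
                f"duplicate {ev!r} event for individual {rid!r}", rownum
            )
        seen_events.add(key)
        if ev == "enroll":
            try:
                rec.exposure_route = ExposureRoute(value)
            except ValueError:
                raise CohortParseError(f"unknown exposure route {value!r}", rownum)
        elif ev == "hatch":
            rec.hatch_age = age
        elif ev == "larva_end":
            rec.larva_end_age = age
        elif ev == "nymph_end":
            rec.nymph_end_age = age
        elif ev == "sex":
            try:
                rec.sex = Sex(value)
            except ValueError:
                raise CohortParseError(f"unknown sex {value!r}", rownum)
        elif ev == "death":
            rec.death_age = age
        elif ev == "eggs":
            try:
                k = int(value)
            except ValueError:
                raise CohortParseError(f"egg count {value!r} is not an integer", rownum)
            if k < 0:
                raise CohortParseError(f"egg count {k} is negative", rownum)
            rec.daily_eggs[age] = k
        elif ev == "viability":
            try:
                tested_s, hatched_s = value.split(":")
                tested, hatched = int(tested_s), int(hatched_s)
            except ValueError:
                raise CohortParseError(
                    f"viability value {value!r} is not 'tested:hatched'", rownum
                )
            rec.viability_trials.append((tested, hatched))
        else:
            raise CohortParseError(f"unknown event_type {ev!r}", rownum)

    recs = [records[rid] for rid in order]
    if treatment is None:
        treatment = ""
    if n_initial is None:
        n_initial = len(recs)
    return Cohort(treatment=treatment, records=recs, n_initial=n_initial)


_RESIDUE_HEADER = [
    "treatment",
    "days_after_application",
    "mortality_pct",
    "is_corrected",
    "fecundity_per_female",
    "viability_pct",
]


def write_residue_csv(rows: Iterable[ResidueAssayRow], path_or_buf: str | TextIO) -> None:
    own = isinstance(path_or_buf, str)
    fh = open(path_or_buf, "w", encoding="utf-8", newline="") if own else path_or_buf
    try:
        w = csv.writer(fh)
        w.writerow(_RESIDUE_HEADER)
        for r in rows:
            w.writerow(
                [
                    r.treatment,
                    r.days_after_application,
                    r.mortality_pct,
                    str(r.is_corrected).lower(),
                    r.fecundity_per_female,
                    r.viability_pct,
                ]
            )
    finally:
        if own:
            fh.close()


def read_residue_csv(path_or_buf: str | TextIO) -> list[ResidueAssayRow]:
    own = isinstance(path_or_buf, str)
    fh = open(path_or_buf, "r", encoding="utf-8", newline="") if own else path_or_buf
    try:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != _RESIDUE_HEADER:
            raise CohortParseError(
                f"unexpected residue header {header!r}, want {_RESIDUE_HEADER!r}", 1
            )
        rows = []
        for rownum, row in enumerate(reader, start=2):
            if not row:
                continue
            try:
                rows.append(
                    ResidueAssayRow(
                        treatment=row[0],
                        days_after_application=int(row[1]),
                        mortality_pct=float(row[2]),
                        is_corrected=row[3].strip().lower() in ("true", "1", "yes"),
                        fecundity_per_female=float(row[4]),
                        viability_pct=float(row[5]),
                    )
                )
            except (ValueError, IndexError) as exc:
                raise CohortParseError(str(exc), rownum) from exc
        return rows
    finally:
        if own:
            fh.close()
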