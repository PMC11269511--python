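"""End-to-end report pipeline: cohorts + residue assays -> tidy tables.

Produces four reports mirroring the shape of a standard life-table
response study:

* ``stage_table.tsv``       — per-treatment stage durations and survival
* ``toxicity_table.tsv``    — Mc, R1/R2(/R3) inputs, Ex, IOBC class
* ``demography_table.tsv``  — R0, r, λ, T with bootstrap SEs and paired
                              test p-values against the control
* ``persistence_table.tsv`` — per-treatment residue Ex by residue age and
                              persistence class

plus ``report.json`` with everything machine-readable and a structured
``pipeline_log.json`` recording every computation and seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bootstrap as bs
from ._util import round_half_up
from .cohort import Cohort, read_cohort_csv, read_residue_csv, validate_cohort
from .lifetable import build_life_schedule, demographic_parameters, survivorship_summary
from .toxicity import (
    ResidueSeries,
    Scheme,
    ToxicityAssessment,
    assess,
    assess_persistence,
    corrected_mortality_pct,
    ReductionInputs,
    score_cohort_pair,
)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    cohort_paths: list[str]
    control_label: str
    residue_path: str | None = None
    bootstrap_B: int = bs.DEFAULT_B
    seed: int = 0
    outdir: str = "demotox_report"
    immature_mortality_exclusion_pct: float = 85.0
    demography_statistics: tuple[str, ...] = ("R0", "r", "lambda", "T")

    def __post_init__(self):
        if self.bootstrap_B < 100:
            raise PipelineError("bootstrap_B must be >= 100")

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        try:
            return cls(**raw)
        except TypeError as exc:
            raise PipelineError(f"bad pipeline config: {exc}") from exc


@dataclass
class _Log:
    entries: list[dict] = field(default_factory=list)

    def add(self, stage: str, **info):
        # sequence index, not wall time: reruns must be byte-identical
        self.entries.append({"step": len(self.entries), "stage": stage, **info})


def _immature_mortality_pct(cohort: Cohort) -> float:
    survived = sum(r.reached_adulthood for r in cohort.records)
    return 100.0 * (1.0 - survived / cohort.n_initial)


def _stage_rows(treatment: str, cohort: Cohort) -> dict:
    n = cohort.n_initial
    hatched = [r for r in cohort.records if r.hatch_age is not None]
    larvae_done = [r for r in cohort.records if r.larva_end_age is not None]
    adults = [r for r in cohort.records if r.nymph_end_age is not None]

    def mean_se(vals):
        if not vals:
            return (float("nan"), float("nan"))
        a = np.asarray(vals, dtype=float)
        se = float(a.std(ddof=1) / np.sqrt(a.size)) if a.size > 1 else 0.0
        return float(a.mean()), se

    egg_d = mean_se([r.hatch_age for r in hatched])
    larva_d = mean_se([r.larva_end_age - r.hatch_age for r in larvae_done])
    nymph_d = mean_se([r.nymph_end_age - r.larva_end_age for r in adults])
    pre_d = mean_se([r.nymph_end_age for r in adults])
    return {
        "treatment": treatment,
        "n_initial": n,
        "hatch_pct": round_half_up(100.0 * len(hatched) / n, 1),
        "egg_duration": round_half_up(egg_d[0], 2) if hatched else None,
        "larva_survival_pct": (
            round_half_up(100.0 * len(larvae_done) / len(hatched), 1) if hatched else None
        ),
        "larva_duration": round_half_up(larva_d[0], 2) if larvae_done else None,
        "nymph_survival_pct": (
            round_half_up(100.0 * len(adults) / len(larvae_done), 1) if larvae_done else None
        ),
        "nymph_duration": round_half_up(nymph_d[0], 2) if adults else None,
        "preadult_duration": round_half_up(pre_d[0], 2) if adults else None,
        "preadult_survival_pct": round_half_up(100.0 * len(adults) / n, 1),
        "n_adults": len(adults),
        "n_censored": cohort.censored_count,
    }


def _toxicity_row(treatment: str, a: ToxicityAssessment) -> dict:
    return {
        "treatment": treatment,
        "scheme": a.scheme.value,
        "mc_pct": round_half_up(a.mc, 2) if a.mc is not None else None,
        "r1": round_half_up(a.r1, 4) if a.r1 is not None else None,
        "r2": round_half_up(a.r2, 4) if a.r2 is not None else None,
        "r3": round_half_up(a.r3, 4) if a.r3 is not None else None,
        "ex_pct": round_half_up(a.ex, 2),
        "ex_raw_pct": round_half_up(a.ex_raw, 2) if a.ex_raw is not None else None,
        "iobc_class": a.iobc_class.value,
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; returns a dict of output paths.

    Deterministic given the config seed: rerunning with the same inputs
    yields byte-identical numeric outputs.
    """
    log = _Log()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    cohorts: dict[str, Cohort] = {}
    for path in config.cohort_paths:
        c = read_cohort_csv(path)
        violations = validate_cohort(c)
        if violations:
            raise PipelineError(
                f"cohort {path} fails validation: "
                + "; ".join(str(v) for v in violations[:5])
            )
        if c.treatment in cohorts:
            raise PipelineError(f"duplicate treatment label {c.treatment!r}")
        cohorts[c.treatment] = c
        log.add("load_cohort", path=str(path), treatment=c.treatment,
                n_initial=c.n_initial)
    if config.control_label not in cohorts:
        raise PipelineError(
            f"control treatment {config.control_label!r} not among inputs "
            f"{sorted(cohorts)}"
        )
    control = cohorts[config.control_label]
    # deterministic report order: control first, then input order
    ordered = [config.control_label] + [
        t for t in cohorts if t != config.control_label
    ]

    # (a) stage-duration/survival table
    stage_df = pd.DataFrame([_stage_rows(t, cohorts[t]) for t in ordered])

    # (b) toxicity table (treated arms vs control)
    tox_rows = []
    for t in ordered:
        if t == config.control_label:
            continue
        variant = "egg" if cohorts[t].exposure_route.value == "topical_egg" else "adult"
        a = score_cohort_pair(control, cohorts[t], variant=variant)
        tox_rows.append(_toxicity_row(t, a))
        log.add("toxicity", treatment=t, variant=variant, ex=a.ex,
                iobc_class=a.iobc_class.value)
    tox_df = pd.DataFrame(tox_rows)

    # (c) demographic parameters with bootstrap SEs and paired tests
    demo_rows = []
    for t in ordered:
        c = cohorts[t]
        imm = _immature_mortality_pct(c)
        if imm >= config.immature_mortality_exclusion_pct:
            log.add("demography_excluded", treatment=t, immature_mortality_pct=imm)
            continue
        sched = build_life_schedule(c)
        params = demographic_parameters(sched)
        median_age, max_life = survivorship_summary(sched)
        row = {
            "treatment": t,
            "immature_mortality_pct": round_half_up(imm, 1),
            "median_survival_age": median_age,
            "max_lifespan": max_life,
            "R0": round_half_up(params.r0, 3),
            "r": round_half_up(params.r, 3),
            "lambda": round_half_up(params.lam, 3),
            "T": round_half_up(params.t_gen, 3),
        }
        for stat in config.demography_statistics:
            est = bs.bootstrap_estimate(c, stat, B=config.bootstrap_B,
                                        seed=config.seed)
            row[f"{stat}_se"] = round_half_up(est.se, 3)
            log.add("bootstrap", treatment=t, statistic=stat, B=est.B,
                    seed=est.seed, se=est.se, n_failed=est.n_failed)
            if t != config.control_label:
                test = bs.paired_bootstrap_test(
                    c, control, stat, B=config.bootstrap_B, seed=config.seed
                )
                row[f"{stat}_p_vs_control"] = round_half_up(test.p_value, 4)
                row[f"{stat}_sig"] = test.p_value < 0.05
        demo_rows.append(row)
    demo_df = pd.DataFrame(demo_rows)

    # (d) persistence table from residue assays
    persist_df = pd.DataFrame()
    residue_long = []
    if config.residue_path:
        rows = read_residue_csv(config.residue_path)
        by_day_control = {
            r.days_after_application: r for r in rows
            if r.treatment == config.control_label
        }
        series_by_treatment: dict[str, dict[int, ToxicityAssessment]] = {}
        for r in rows:
            if r.treatment == config.control_label:
                continue
            ctrl = by_day_control.get(r.days_after_application)
            if ctrl is None:
                raise PipelineError(
                    f"no same-day control row for {r.treatment} at "
                    f"{r.days_after_application} DAA"
                )
            mc = (
                r.mortality_pct
                if r.is_corrected
                else corrected_mortality_pct(ctrl.mortality_pct, r.mortality_pct)
            )
            a = assess(
                ReductionInputs(
                    mc=mc,
                    fecundity_t=r.fecundity_per_female,
                    fecundity_c=ctrl.fecundity_per_female,
                    viability_t=r.viability_pct,
                    viability_c=ctrl.viability_pct,
                ),
                Scheme.extended_lab,
            )
            series_by_treatment.setdefault(r.treatment, {})[
                r.days_after_application
            ] = a
            residue_long.append(
                {
                    "treatment": r.treatment,
                    "days_after_application": r.days_after_application,
                    "mc_pct": round_half_up(mc, 1),
                    "ex_pct": round_half_up(a.ex, 1),
                    "iobc_class": a.iobc_class.value,
                }
            )
        persist_rows = []
        for t, assessments in series_by_treatment.items():
            res = assess_persistence(ResidueSeries(t, dict(sorted(assessments.items()))))
            persist_rows.append(
                {
                    "treatment": t,
                    "days_to_harmless": res.days_to_harmless,
                    "persistence_class": res.persistence_class.value,
                    "warnings": "; ".join(res.warnings),
                }
            )
            log.add("persistence", treatment=t,
                    persistence_class=res.persistence_class.value,
                    days_to_harmless=res.days_to_harmless)
        persist_df = pd.DataFrame(persist_rows).sort_values("treatment")

    paths = {}
    for name, df in [
        ("stage_table", stage_df),
        ("toxicity_table", tox_df),
        ("demography_table", demo_df),
        ("persistence_table", persist_df),
    ]:
        p = outdir / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=False)
        paths[name] = str(p)
    report = {
        "config": {
            "control_label": config.control_label,
            "bootstrap_B": config.bootstrap_B,
            "seed": config.seed,
            "immature_mortality_exclusion_pct": config.immature_mortality_exclusion_pct,
        },
        "stage_table": stage_df.to_dict(orient="records"),
        "toxicity_table": tox_df.to_dict(orient="records"),
        "demography_table": demo_df.to_dict(orient="records"),
        "residue_assessments": residue_long,
        "persistence_table": persist_df.to_dict(orient="records"),
    }
    report_path = outdir / "report.json"
    report_path.write_text(json.dumps(report, indent=2, default=str) + "\n")
    paths["report"] = str(report_path)
    log_path = outdir / "pipeline_log.json"
    log_path.write_text(json.dumps(log.entries, indent=2, default=str) + "\n")
    paths["log"] = str(log_path)
    return paths
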