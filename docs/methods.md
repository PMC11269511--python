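# Methods

This note documents the models, conventions and numerical choices behind
demotox, and what its synthetic-data tests do and do not establish about
real experiments.

## Cohort data model

A cohort is a fixed number of individuals followed by daily census from
the start of exposure. Age 0 is the day of oviposition for egg-exposure
cohorts and the day of adult emergence for adult-exposure cohorts; all
ages are integer days. An individual found dead at a census carries that
census day as `death_age` and is treated as alive at every earlier age;
one found dead on a stage-transition day is assigned to the earlier stage
(the conservative choice — the later boundary stays unset). Eggs that have
not hatched by day 4 are recorded dead at age 4 with no hatch age.
`death_age = None` marks right-censoring (alive at the last census, or
lost); censored individuals contribute to the survival schedules up to
their last observed age and drop out of both the numerator and denominator
of the fecundity schedule afterwards. The number of censored individuals
is carried on every schedule so users can judge the impact. How escaped
individuals were handled is rarely reported in this literature; this
censoring convention is the package's own choice.

## Life-table schedules

With *n* initial individuals, the age-stage occupancy is
`sxj[x, j] = (alive in stage j at age x) / n` over the stages egg, larva,
nymph, adult female, adult male; survivorship is `lx = Σj sxj` and
fecundity `mx[x]` is total eggs laid at age x divided by the number of
individuals alive at age x. Both sexes enter every denominator (the
two-sex convention): `mx` is eggs per living individual, not per female,
so sex ratio and male survival propagate into the demographic parameters
without separate bookkeeping. `l0 = 1` whenever no individual is recorded
dead at age 0, which holds for every cohort the simulator produces.

## Demographic parameters

- `R0 = Σx lx·mx` — expected lifetime offspring per initial individual.
- `r` solves `Σx exp(−r(x+1))·lx·mx = 1`. The (x+1) exponent reflects
  age-from-zero day indexing: reproduction recorded "at age 0" happens at
  the end of the first day and is discounted one full day. The classic
  textbook form without the +1 corresponds to indexing ages from 1; with
  consistent indexing the two give the same growth process, but the
  convention matters when comparing numerical outputs, so it is stated
  prominently.
- `λ = exp(r)`; `T = ln(R0)/r`, and in the replacement-rate limit
  (|r| < 1e−9) the fecundity-weighted mean reproductive age
  `Σ (x+1)·lx·mx / R0`, which is the limit of `ln(R0)/r` as r → 0.

The left side of the renewal equation is strictly decreasing in r, so the
real root is unique. It is found by Brent's method on the bracket [−1, 2]
day⁻¹, widened geometrically in the rare case a schedule's root lies
outside (arthropod cohorts with |r| > 1 per day do not occur in practice);
the residual at the returned root must be below 1e−10 or an error naming
the bracket is raised. Negative r (declining cohorts, R0 < 1) is an
expected outcome for heavily stressed cohorts, not an error; R0 = 0
(sterile cohort) has no root and raises.

## Bootstrap inference

The resampling unit is the whole individual: each replicate draws
`n_initial` records with replacement and recomputes the statistic from
scratch, so all within-individual dependence (development, fecundity and
longevity of the same mite) is preserved. The standard error is the SD of
replicate values and the interval the 2.5/97.5 percentiles; the paired
test resamples both cohorts independently and uses the two-sided
percentile p-value `2·min(P(diff ≤ 0), P(diff ≥ 0))`, floored at 1/B so
that zero lies outside the 95% percentile interval of differences iff
p < 0.05 up to the 1/B resolution. The literature this serves rarely
defines its paired-test construction precisely; this two-sided percentile
rule is the package's documented choice. Replicates on which a statistic
is undefined — no surviving females for a longevity mean, R0 = 0 for r —
are dropped and counted (`n_failed`) rather than imputed, the
replicate-level analogue of estimating demographic parameters only for
treatments whose immature mortality stays below 85%; more than half
undefined raises a degenerate-estimate error. The default B = 100,000
matches field practice for these SEs; test suites use B = 1,000–2,000,
which is the only scaled-down setting in the package. One root seed drives
a single NumPy generator consumed in replicate order, so results are
exactly reproducible.

No BCa or studentized intervals are provided: the downstream comparisons
are percentile-based.

## Toxicity scoring

Corrected mortality uses Henderson–Tilton,
`Mc = 100·(1 − (Co_before·T_after)/(Co_after·T_before))`, clamped to
[0, 100]; with equal before-counts it reduces to the Abbott /
Schneider–Orelli correction on survival fractions, which is the form used
for residue assays reported as mortality percentages against a same-day
control.

The reduction coefficient is `Ex = 100 − (100 − Mc)·R1·R2(·R3)`.
Egg-stage assessments use the three-ratio form with R3 = female adult
longevity ratio; adult-stage and residue (extended-laboratory)
assessments use the two-factor form without R3 — the published adult
values reproduce exactly under the two-factor form, and the residue
scheme is defined with it. Which sex's longevity enters R3 is not settled
in the literature; female-only is used here, as females drive population
growth. Ratios are used as computed and may exceed 1 (a treatment can,
e.g., lengthen male life); Ex is clamped to [0, 100] for classification
and the unclamped value is reported alongside.

IOBC classification bands, as implemented:

- laboratory scheme: I (harmless) Ex < 30; II (slightly harmful)
  30 ≤ Ex < 80; III (moderately harmful) 80 ≤ Ex ≤ 99; IV (harmful)
  Ex > 99;
- extended-laboratory scheme: I Ex < 25; II 25 ≤ Ex ≤ 50; III
  50 < Ex ≤ 75; IV Ex > 75.

The band edges as conventionally printed leave gaps (79–80 and 99–100 in
the laboratory scheme, 50–51 in the extended one); the half-open
intervals above close them and are consistent with every published
(Ex, class) pair this package was checked against, with one known
exception: an extended-laboratory Ex of 90.1 printed as class III in one
source, which the band definition itself makes class IV. The package
follows the band definition.

Persistence: `days_to_harmless` is the earliest assessed residue age
classified harmless (I) with no later harmful assessment; classes are
A < 5 d ≤ B ≤ 15 d < C ≤ 30 d < D, with D also covering deposits never
observed harmless within the series. A non-monotone recovery (harmless
then harmful again) falls back to the day after the last harmful
assessment and emits a warning — assay noise, not biology, is the usual
cause.

## Synthetic cohort generator

The generator emulates the structure such experiments assume: independent
individuals; Bernoulli survival gates per immature stage; stage durations
as gamma draws rounded to the nearest day with a stage-specific floor
(1 day for egg and nymph, 0 for the short larval stage) — daily-census
granularity; sex assigned at adult emergence (immatures are not sexed, so
immature deaths carry sex "unknown"); adult longevity as a discretized
gamma per sex; daily egg counts Poisson around the deterministic unimodal
curve `m(t) = a·t·exp(−b·t)` of adult age t after a pre-oviposition
period, parametrized by its peak rate and peak age (b = 1/peak_age); and
each egg an independent viability trial. Overdispersion in fecundity is
not modelled — published schedules report only daily means with SEs, and
Poisson is the simplest model consistent with them; real counts are often
noisier, so bootstrap SEs on real data may exceed those seen in
simulation. No spatial structure, prey dynamics, or mechanistic residue
decay is simulated.

Because every ingredient is discrete and independent, the exact lx/mx
schedules follow by convolution of the stage-duration pmfs mixed over the
death-stage probabilities, and the analytic `R0 = Σ lx·mx` equals
pre-adult survival × sex ratio × expected per-female lifetime egg output.
These exact schedules are what estimator tests recover against.

### Presets

`control-like` encodes an unstressed phytoseiid cohort: hatch probability
1.0, pre-adult survival 0.94, pre-adult period ≈ 4.5 d, sex ratio 0.68
female, per-female fecundity peaking 2.15 eggs/day at adult day 10
(≈ 28 eggs/female lifetime; the population-level mx schedule, which
divides by all living individuals, then peaks near 1.3 eggs/day), female
adult longevity mean 18.3 d (shape 5), male 12.5 d (shape 12), egg
viability 0.97. These give analytic R0 ≈ 18, a 50%-survivorship age of
19 days and r ≈ 0.21/day — the magnitudes of a healthy predatory-mite
colony. The gamma shapes are chosen to match the spread such cohorts
show (duration SEs of a few tenths of a day; adult longevity SD of
several days); they are the package's calibration, not measured values.
`stressor-like` halves survival and adult longevity and quarters
fecundity (analytic R0 ≈ 0.9 — a collapsing cohort); `stressor-mild` is
intermediate (R0 ≈ 6.5). What passing recovery tests on these presets
shows is that the estimation pipeline is correct for data with this
structure; it does not validate the biological realism of any particular
experiment, nor cover overdispersed fecundity or correlated individual
frailty.

## Pipeline and reporting

The `report` pipeline loads validated cohort CSVs plus an optional
residue-assay CSV and emits four tables (stage durations/survival;
Ex/IOBC toxicity; demographic parameters with bootstrap SEs and paired
tests against the control; residue Ex and persistence classes) plus a
machine-readable report and a structured log of every computation with
its seed. Treatments with immature mortality at or above 85% (the
conventional estimability threshold, configurable) are excluded from the
demographic table but still scored for Ex. Reported decimals follow the
conventional precision of such tables (1–2 dp for percentages, 3 dp for
r and λ) using round-half-up. Reruns with the same config and seed are
byte-identical.

## Problem sizes in the test suite

Tests use cohorts of 15–500 individuals and B = 100–2,000 bootstrap
replicates; the solver-vs-oracle comparison runs 100 random schedules at
1e−6 agreement; parameter recovery uses 50 seeded cohorts of 500; CI
coverage uses 200 cohorts of 50 at B = 1,000; Monte-Carlo checks of the
analytic schedules use 10,000–20,000 individuals. These sizes make the
full suite run in well under a minute while leaving the statistical
assertions comfortably powered.

## Known limitations

- Fecundity is conditionally Poisson; no overdispersion or individual
  frailty.
- The adult-route simulator has no acute-mortality knob (all simulated
  adults survive the first day); acute adult kill enters through real
  data or the summary-level scoring path.
- Life-table schedules treat heavy censoring crudely (censored
  individuals simply leave the risk set); with many escapes a
  Kaplan–Meier-style treatment would be preferable.
- The extended-laboratory classification follows the band definition even
  where one published value was printed with a different class (see
  above).
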