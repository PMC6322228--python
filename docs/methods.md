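# Methods

## Overview

`nimargin` sets a non-inferiority margin by equipoise in lifetime
quality-adjusted outcomes. Four steps:

1. a deterministic cohort model maps (exam schedule, target cumulative
   event rate) to lifetime person-time, events and exams per 1000
   patients;
2. QALY accounting converts the trace into per-1000 totals: life-years
   minus losses from surveillance exams, exam complications, and cancer
   treatment;
3. a root finder locates the alternative-arm event rate `p_A*` at which
   the two arms' QALYs (or net monetary benefit) are equal; the margin
   is δ = p_A* − p_S;
4. δ feeds the two-proportion non-inferiority sample-size formula, with
   a Monte-Carlo power simulation as an independent check.

The cohort core is deterministic (state-fraction bookkeeping, not
microsimulation), so the equipoise search is noise-free and
bit-reproducible. The only randomness in the package is the power
simulator, which is seeded.

## Cohort model

States: susceptible (alive, cancer-free) → diagnosed → dead (other
cause, cancer, fatal exam complication). Monthly cycles
(`cycle_length = 1/12` y) from the start age (50) to a terminal age of
100, with half-cycle-corrected person-time; monthly resolution keeps
the outcome gap smooth enough for root finding on the event rate.

**Other-cause mortality** is Gompertz by default,
μ(a) = a₀·exp(b·(a − 50)) with a₀ = 0.009/y and b = 0.09/y, chosen so
the residual life expectancy at 50 is ≈ 22.4 years — the magnitude of a
general adenoma-surveillance cohort (≈ 22,300 life-years per 1000).
A tabulated life table (age, annual death probability) can be supplied
instead.

**Cancer incidence** is a single age-exponential diagnosis hazard
(doubling every 12 years; level immaterial) multiplied by a calibrated
factor ψ so that the cohort's cumulative incidence over the first
10 years — *in the presence of competing other-cause mortality*, i.e.
the real-world risk of being diagnosed — equals the requested target.
Calibration is bracketed Brent root finding; the achieved incidence is
within 1e-10 of the target (contract: 1e-8). ψ stays in force for the
remaining lifetime: how incidence beyond the trial horizon relates to
the dialled 10-year risk is a genuinely open modelling choice, and a
constant multiplier is the simplest lifetime extension. One-way
sensitivity to that choice is not built in.

**Exams** occur at start_age + k·interval (k ≥ 1) up to the stop age,
only for alive, not-yet-diagnosed persons. Each exam multiplies the
cancer hazard by (1 − ρ·ε) until the next scheduled exam (or for
`interval` years after the last): ρ = 0.5 per-exam protection by
default, ε a sensitivity multiplier swept ±5% in the uncertainty
analysis. Because each arm is recalibrated to its own target rate, ρ·ε
mainly shapes the timing of incidence and the post-surveillance
lifetime burden, not the 10-year total. Schedules are fixed by the arm,
never findings-dependent — the design randomises the schedule itself.
Each exam also carries a fatal complication probability
(polypectomy_fraction × 1/30,000), applied as an immediate mortality
stream; the dead accrue no further person-time, so a fatal complication
implicitly costs its remaining life expectancy.

**Diagnosed persons** face a constant excess mortality of 0.09/y for a
cure horizon of 5 years (≈ 64% 5-year survival, a plausible all-stage
colorectal figure), then revert to background mortality ("cured").
Diagnosed person-time is partitioned exactly into: initial phase (first
year), continuing phase (year 1 to cure), cured (no disutility, no
cost), and terminal phase — the last year before a cancer death, carved
out of the other phases by attributing to each cancer death the
person-time of its final 12 cycles. The partition is exact, so with all
phase disutilities at 1.0 the treatment loss equals the pre-cure
diagnosed person-time.

Conservation (all state fractions sum to 1) holds to < 1e-12 at every
cycle, enforced in tests.

## QALY and cost accounting

Per-exam disutility (days) = scaling × (21 d × 0.1 + 2 d × 0.5) =
3.1 × scaling; `scaling` represents a population percentile of the
burden distribution (0.8 / 1.2 conventional alternates). Complication
probability per polypectomy exam grows exponentially from 0.002 at age
40 to 0.038 at age 85 (extrapolated outside, capped at 1); each
non-fatal complication costs 14 days of utility;
`polypectomy_fraction = 0.3` of exams involve polypectomy — that
fraction is a documented configuration knob, not an estimate. Days
convert to years at 365.25.

Treatment-phase disutilities (0.30 initial / 0.10 continuing / 0.45
terminal) and unit costs (€500 per colonoscopy, €5,000 per
complication, €25,000 / €2,500 / €30,000 per phase-year, willingness to
pay €20,000 per QALY) are stylised placeholders of conventional
magnitude: the equipoise *mechanics* do not depend on their exact
values, and every test that touches them is property-based, not
value-based. Discounting (continuous, default rate 0) is supported and
applied uniformly to person-time, losses and costs.

## Equipoise solver

gap(p_A) = outcome(alt at p_A) − outcome(std at p_S), per 1000, with
the standard arm evaluated once and cached. The NMB gap is
(λ·ΔQALY − ΔCost)/λ, so one tolerance (1e-4 QALYs per 1000) serves both
criteria. Equipoise is gap = 0 exactly — no acceptable-loss slack. The
bracket starts at [p_S, p_S + 0.01] and doubles in width to at most
p_A = 0.2; a gap that never changes sign raises an explicit error
("alternative dominates" / "never non-inferior"). Brent's method on the
bracket; the tolerance sits on the gap rather than on p_A because the
gap's slope varies across scenarios. When the alternative is weakly
cheaper at every rate, the NMB margin is provably at least the QALY
margin (the cost saving adds a positive term to the gap).

## Trial design

n/arm = ⌈(z₁₋α + z₁₋β)²·(p_S(1−p_S) + p_A(1−p_A))/δ²⌉ with the assumed
true p_A equal to p_S (equal true efficacy under the alternative
hypothesis) — the convention under which the published hand-calculated
sizes (19,234; 8,826; 16,754) reproduce exactly. Normal quantiles are
rounded to 3 decimals (1.645, 1.282) by default for the same reason;
full precision shifts n by ≤ 5 per arm (asserted in tests). The power
simulator draws binomial counts per arm and applies the one-sided Wald
test with unpooled standard error — matching the formula's variance —
rejecting when (p̂_A − p̂_S − δ)/SE < −z₁₋α.

## Uncertainty sweeps

`run_sweep` repeats the solve over a grid of disutility scalings
(default 0.5–1.5) × sensitivity multipliers (default 0.95–1.05),
independently per point (execution order cannot affect output); failures
are recorded per row with a status code, never dropped. The
conservative sample size is reported as the maximum n_total over the
grid — a summary, not a decision rule. Output is a tidy CSV and an
optional annotated equipoise-line figure.

## What the defaults do and do not show

The default scenario reproduces the *structure* of a real
polyp-surveillance design problem — schedules, burden decomposition,
complication risk, the 1% standard-arm rate and the published
sample-size arithmetic — but the cohort model is a reduced form: a
single calibrated diagnosis hazard instead of an adenoma–carcinoma
natural history, no stage distribution, no findings-dependent
surveillance, scalar protection instead of test characteristics.
Absolute QALY totals and the solved margin therefore carry the model's
own calibration (the defaults give δ ≈ 0.35% QALY / 0.64% NMB) and
should be read as outputs of *this* model, not of any published
microsimulation. Passing tests demonstrate the framework's internal
identities, orderings and solver correctness, not external validity of
the natural-history parameters.

## Numerical choices

- Cycle alignment of exam ages is checked to 1e-6 cycles; misalignment
  is a configuration error.
- Calibration: Brent on [0, ψ_hi] with doubling upper bracket; the
  unreachable case reports the achievable incidence range.
- Ceiling in the sample size forgives floating-point undershoot within
  1e-9 of an integer.
- Degenerate Wald statistics (SE = 0) reject iff the point estimate
  difference is below δ.
- Diagnosed-cohort responses are precomputed once per (natural history,
  life table, start age) and reused across calibration and the solve;
  results are independent of this caching.

## Known limitations

- Post-horizon incidence extension by constant multiplier (see above).
- Terminal-phase attribution assumes each cancer death's final year is
  representative person-time; deaths within a year of diagnosis get a
  correspondingly truncated terminal phase.
- No probabilistic sensitivity analysis; sweeps are one-way and
  deterministic.
- Treatment disutilities and costs are placeholders; margins under the
  NMB criterion inherit their uncertainty directly.
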