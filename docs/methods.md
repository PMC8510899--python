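# Methods

## Model structure

The engine is a discrete-time Markov cohort model with 6-month cycles. The
state space comprises:

- `well`;
- a hip-fracture track of 16 tunnel states (one per cycle since the event,
  covering the 8-year excess-mortality window) followed by a terminal
  `post_hip` state;
- an identical vertebral track;
- an "other"-fracture (wrist/distal forearm) track of 2 tunnel states that
  returns to `well` after one year;
- an absorbing `dead` state.

Tunnels exist solely to clock time since fracture: the first two tunnels of a
track are the first year after the event (first-year mortality relative
risks, first-year costs and first-year utility multipliers apply); later
tunnels carry subsequent-year inputs while inside the excess-mortality
window; the terminal post-fracture states revert to background mortality but
keep subsequent-year costs and utility multipliers for the remainder of life
(the published inputs give those no stopping point).

The cohort starts 100% well at age 77 and is propagated to age 110, by which
point living occupancy is below 10⁻³; the residual is simply not propagated
further (no terminal reward). Age advances 0.5 years per cycle and all
age-banded lookups (mortality, costs, utilities) use closed-open bands with
the top band open-ended.

### Severity hierarchy and correction factor

Occupants of a fracture track can sustain fractures of the same or higher
severity only: hip-state occupants may re-fracture a hip (re-entering hip
year 1) but cannot sustain vertebral or "other" fractures; vertebral-state
occupants may sustain a hip fracture but not an "other" fracture; vertebral
re-fracture is not modelled; "other"-state occupants simply complete their
year. Allowing subsequent hip fracture matters: without it the model
understates 10-year hip incidence by roughly 8 per 1,000 in both arms
relative to the published counts.

The vertebral and "other" fractures the hierarchy hides are restored by a
correction factor computed after the chain has run: per cycle, overlooked
vertebral events equal hip-track occupancy times the cycle's vertebral entry
probability, and overlooked "other" events equal hip- plus vertebral-track
occupancy times the "other" entry probability. Each overlooked event accrues
its first-year cost and first-year utility decrement over two cycles and,
for vertebral events, subsequent-year cost and utility decrements over the
host cohort's remaining lifetime, using the trace's cohort survival as the
surviving fraction (an approximation: hip-state hosts die somewhat faster
than the cohort average). Excess mortality of overlooked events is not fed
back into the trace (which is already closed); instead the expected excess
deaths — events × (first-year RR − 1) × annual well mortality, floored at
zero because the "other" RR at ages 70–79 is 0.97 — are converted to a QALY
loss via the discounted remaining QALY expectation of a well-state survivor.
All correction-factor quantities are discounted at the cycle of occurrence.
These events also count toward the reported 10-year fracture incidence.

### Competing risks and rate conversions

Annual rates and probabilities are converted assuming constant hazards
within a cycle: p = 1 − exp(−rate × Δt), and relative risks multiply rates
(probabilities are converted to rates before scaling). Competing transitions
out of a state are each converted independently; the leftover probability
stays (or advances along the track). The outflow sum never approaches 1 at
published magnitudes; a proportional rescale guards the degenerate case.

No half-cycle correction is applied: rewards accrue on state occupancy at
cycle start and the whole cycle's reward takes that cycle's discount factor
(1 + r)^(−cycle × Δt). With 6-month cycles the half-cycle adjustment is well
inside the reproduction tolerance, and the convention keeps every reported
number a pure function of the published inputs.

## Treatment persistence and effect offset

The treated cohort receives doses at cycles 0–9 (5 years). Everyone is
persistent for the first two cycles (the cohort is defined by having
received at least two doses); from cycle 2 the persistent fraction decays by
the per-cycle discontinuation probability 1 − exp(−0.317 × 0.5) = 14.7%.
Patients who stop — and course completers at cycle 10 — pass through four
offset strata in consecutive cycles, then contribute no effect.

The offset stratum k ∈ {1..4} carries the hazard multiplier
HR + (1 − HR)(k − 1)/4: the residual benefit is full in the first uncovered
cycle and declines linearly, first reaching zero exactly two years after the
last dose. The alternative (right-endpoint) discretisation
HR + (1 − HR)k/4 was evaluated and rejected: it shortens the effective
benefit by one cycle per patient and moves the base case outside the
reproduction tolerance (total fractures avoided 37.9 vs the published 45
per 1,000; ICER 20,548 vs 16,743).

Persistence enters the chain as cycle-level stratum weights applied as a
weighted-mean hazard multiplier, independent of health state. For expected
incidence this is exact up to a Jensen gap of order (rate × Δt)² × var(m),
about 10⁻⁶ here. The off-treatment arm's single dose grants the full hazard
ratio in cycle 0 only, with no offset tail.

Drug cost ($200/dose) and management costs (nurse visit every cycle, routine
visit every second cycle starting at cycle 0, DXA scan every fourth cycle
starting at cycle 0) accrue to alive, persistent patients during the course;
the off-treatment arm accrues one dose plus a nurse and routine visit at
cycle 0. This schedule reproduces the published drug-cost and
incremental-cost figures almost exactly; the treatment-arm management total
comes out ≈$132 against a published $122, the one line where the published
visit timing cannot be fully pinned down from the inputs.

## Parameters

All defaults are the published point estimates; the ones that drive results:

| parameter | default | units / note |
|---|---|---|
| baseline fracture rates (hip/vert/other) | 0.017 / 0.017 / 0.004 | events per patient-year, held age-constant in the base case |
| hazard ratios on treatment | 0.62 / 0.63 / 0.62 | nonvertebral HR proxies "other" |
| discontinuation rate | 0.317 | per patient-year, from cycle 2 |
| offset duration | 2 | years of linear benefit decline |
| excess mortality window | 8 / 8 / 1 | years after hip / vertebral / other |
| discount rate | 3% | per annum, costs and effects |
| horizon | age 77 → 110 | 66 cycles |
| WTP threshold | $30,038/QALY | GDP per capita, 2020 |

## Probabilistic sensitivity analysis

Every uncertain input is sampled independently: lognormal for ratios (HRs
with CI-derived log-scale σ and median at the point estimate; mortality RRs
moment-matched with the 10%-of-mean rule), gamma for rates (CI-derived SE)
and all costs (10% rule), beta for well utilities and mortality
probabilities (10% rule) and utility multipliers (CI-derived SE). Structural
quantities (discontinuation rate, offset, discount rate, cycle length) are
not sampled. Each of the 1,000 iterations re-runs both arms in full; the
CEAC reports the fraction of iterations with positive net monetary benefit
λ·ΔQALY − ΔC over λ from 0 to $60,000 in $1,000 steps. A fixed seed makes
the PSA bit-reproducible.

## Scenarios

*Perfect persistence* sets the discontinuation rate to zero (all treated
patients complete the course, then the offset). *Age-adjusted rates* scales
the baseline fracture rates each cycle by a user-supplied age-band relative
incidence, renormalised to 1 at the start-age band; no default multipliers
ship because the external age-incidence values are not part of the input
set — the example script uses illustrative synthetic multipliers.

## The microsimulation oracle

The patient-level simulator draws individual trajectories with the same
per-cycle probabilities, persistence mechanics (per-patient geometric
discontinuation, individual 4-cycle offset) and reward rules as the cohort
engine. It emulates what the cohort model computes in expectation — it adds
no heterogeneity beyond age progression, no real-world features (secular
mortality trends, adherence patterns, fracture-dependent discontinuation)
absent from the cohort model. Agreement between the two therefore validates
the recursion's bookkeeping (including the weighted-multiplier persistence
approximation), not the model's fidelity to real patients. The comparison
covers Markov-visible quantities; the correction factor is a cohort-level
construct (its lifetime windows use cohort survival tails) and is not
re-derived per patient. `random_parameters` generates bracketed random input
sets (rates ×[0.25, 4], HRs in [0.3, 1.0], mortality ×[0.5, 2], costs
×[0.25, 4], utilities in [0.3, 0.9]) for property testing across the input
space, at sizes (6,000–200,000 patients) chosen so Monte-Carlo error is
small against the tolerances being checked.

## Numerical conventions and degenerate inputs

- Occupancy conservation holds to 10⁻¹² per cycle; the dead state is
  monotone by construction.
- Zero rates, zero mortality and zero discounting are all valid inputs and
  exercised in tests (null dynamics, undiscounted life-year identities).
- ΔQALY = 0 yields no ICER division: the summary carries a
  dominance/undefined label instead.
- Cumulative-incidence dominance of the treated arm holds for total
  (Markov-visible + correction-factor) events; the visible count alone can
  cross over under extreme inputs because the arm with more hip occupancy
  hides more of its vertebral burden.
- Sampled or user-overridden point estimates drop their printed CI bounds
  (the CI-brackets-value invariant applies to the published inputs).

## Known limitations

- The correction factor's lifetime windows use cohort-average survival for
  the host states; hosts' true excess mortality would shrink those windows
  slightly.
- Fracture risk and treatment discontinuation are independent; stopping
  treatment upon fracture is not modelled.
- No vertebral re-fracture, no fracture transitions out of the "other"
  state (its occupancy is < 0.5% for two cycles), no adverse events, no
  societal-perspective costs.
- Base-case fracture rates are age-constant; the age-adjusted scenario
  exists precisely because this understates late-life risk.
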