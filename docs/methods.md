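# Methods

## Decision problem

Patients with colorectal cancer under staging for liver metastases
(prevalence of resectable CRLM: 27.5%) are imaged with one of three
modalities. The question is which modality minimises long-run cost per
quality-adjusted life year from a US-payer perspective, given each test's
sensitivity/specificity, the cost of timely versus delayed resection, and
the downstream consequences of missed or falsely suspected metastases.

## Decision tree (cycle 0)

For a strategy with sensitivity *se*, specificity *sp* and prevalence *p*:

| branch | mass | destination | upfront cost |
|---|---|---|---|
| true positive | p·se | resection: success (0.70) → resected, failure → recurrence | imaging + $21,592 |
| false negative | p·(1−se) | undiagnosed tumour | imaging |
| true negative | (1−p)·sp | tumour-free | imaging |
| false positive | (1−p)·(1−sp) | tumour-free | imaging + FP work-up |

Upfront (cycle-0) costs are undiscounted. The printed aggregate resection
cost ($21,592) is used as the one-time resection price; the itemised
components (hepatic resection $4,450 + 7 hospital days × $2,606 = $22,692)
are carried as separate parameters but do not enter the true-positive
pathway, since the aggregate is the figure the source tabulates.

## Markov model (annual cycles)

States: tumour-free, undiagnosed tumour, resected, recurrence, death
(absorbing). During cycle *t* the cohort is aged `start_age + t`; the
background annual death probability q(age) comes from the life table and
combines with disease-specific mortality as independent competing risks,
`1 − (1−p_disease)(1−q)`. Transitions:

- **tumour-free** → death at q(age) only; utility 1, cost 0.
- **undiagnosed tumour** → death at `1−(1−0.2417)(1−q)`; surviving patients
  are clinically detected with probability `p_detect` per cycle and undergo
  delayed resection ($28,069.60 = 1.3× timely; success 0.70 → resected,
  failure → recurrence). While undetected: utility 0.85 and the
  `undetected_annual_cost` running cost (see calibration). The delayed
  resection charge is booked in the cycle the transition leaves.
- **resected** → recurrence at the annualised recurrence probability;
  death at q(age); utility 0.78, cost 0.
- **recurrence** → death at `1−(1−p_death_recurrence)(1−q)`; utility 0.65,
  running cost $63,063/year (annual expenses with active CRLM).

The 62% recurrence probability after resection is treated as a 5-year
cumulative figure and annualised as `1−(1−0.62)^(1/5) = 0.175944`
(configurable to `annual`); applying 62% per year would leave almost no
one recurrence-free and is inconsistent with the reported effectiveness.

Cycle-*t* accruals are occupancy-weighted state costs and utilities
discounted by `(1.03)^(−t)` (t = 0 undiscounted); no half-cycle correction
is applied. Occupancy vectors are checked to sum to 1 (tolerance 1e-12)
and any transition row deviating from 1 by more than 1e-12 is an internal
error, not a warning.

## Life table

`data/lifetable_us2015_synthetic.csv` ships with the package: a synthetic
all-population table for ages 65–100 built from a Gompertz fit
`q(age) = exp(−10.491 + 0.0947·age)`, matching the magnitude and age
gradient of the published 2015 US period life table (q(68) ≈ 0.017,
q(100) ≈ 0.36). Ages beyond 100 are treated as certain death, which closes
the model for any horizon. Users can substitute any `age,qx` CSV.

## Parameter distributions

Probabilities and utilities are beta, costs gamma, both fitted by the
method of moments: beta `α = m·ν, β = (1−m)·ν` with `ν = m(1−m)/s² − 1`;
gamma `k = (m/s)², θ = s²/m`. Zero dispersion (and fixed settings:
discount rate, WTP, horizon, start age) gives a point mass. Infeasible
moment combinations (`s² ≥ m(1−m)`, or a degenerate mean with s > 0) are
rejected at construction, so no draw can ever be invalid. Where no
standard error is published, the default dispersion is 20% of the mean,
capped to keep beta moments feasible.

## Calibration configuration

The source text leaves four structural choices open, and its reported
~8.5 QALYs cannot arise from a literal 5-year horizon with utilities ≤ 1,
so the effective horizon of the original implementation is unknown. The
committed file `config/calibration.yaml` fixes, once:

| setting | value | rationale |
|---|---|---|
| horizon | 13 annual cycles | reproduces reported costs and QALYs simultaneously; treated as the effective horizon of the original model |
| undetected_annual_cost | $63,063 | missed metastases are active CRLM; without this cost the lowest-sensitivity strategy becomes the cheapest and the reported dominance ordering cannot arise |
| p_death_recurrence | 0.34971 | annualised from the untreated 3-year overall survival of 27.5% (`1−0.275^{1/3}`); the tabulated 24.17% is retained for the undiagnosed state |
| fp_workup_cost | $22,692 | false positives proceed to the itemised surgical work-up (resection + 7 hospital days); a cheap confirmatory scan would make specificity economically irrelevant, contradicting the reported tornado |
| p_detect | 1.0 | missed metastases are found at the next annual evaluation |

The same file sets per-parameter PSA dispersions (accuracy SEs 0.02–0.11,
imaging costs 15%, surgical costs 5%, long-term costs 8%, utilities 6%,
probabilities 4%), calibrated once so the 50,000-iteration PSA reproduces
the reported acceptability shares; the four structural values above are
assumptions and are not sampled. Under this configuration the model gives
$45,270/$44,747/$46,126 and 7.93/7.94/7.93 QALYs (CE-CT/MRI/PET-CT) with
MRI strictly dominant, and PSA shares ≈ 6.6/83.6/9.8%.

## Economic analysis

ICERs are computed pairwise with dominance flags (cheaper *and* more
effective → dominant; equal effects → undefined, cheaper preferred). The
efficiency frontier removes strictly dominated options, then applies the
standard extended-dominance sweep until frontier ICERs increase strictly
with cost. All cost/effect ties — deterministic and in PSA winner counts —
are broken by lexicographic strategy name, making every output
order-independent and reproducible.

## Sensitivity analyses

*Tornado*: each sampled parameter is varied ±25% of its base value
(clipped to [0,1] for beta-family parameters, ≥0 for costs). The metric is
the incremental NMB between a fixed strategy pair — by default the two
base-case leaders, and in the reported analysis MRI vs PET/CT, the
comparison the reference figure plots — because MRI's dominance leaves the
ICER undefined at base case. Pairwise ICER endpoints are reported where
defined. *Two-way*: the max-NMB winner on a parameter grid. *PSA*: one
seeded generator draws all sampled parameters per iteration in table
order; the draws are shared across strategies, so results do not depend on
evaluation order and reruns with the same seed are bit-identical. A
vectorised batch engine evaluates all iterations at once; a regression
test pins it to the reference cohort recursion at 1e-9.

## Microsimulation oracle

`synthetic.microsim_oracle` simulates individual trajectories by sampling
initial branches from `initial_allocation` and next states from the rows
of `transition_matrix` — the same objects the cohort engine uses, so the
two cannot drift apart silently — with identical discounting and event
costs. The cohort totals agree with the oracle means within 3 standard
errors at n = 100,000 across random parameter tables (tested). The
synthetic generators (random valid tables, Gompertz life tables) emulate
the *structure* of real inputs, not their joint clinical plausibility:
passing property tests shows the engine is internally consistent over the
legal input space, not that any particular table is clinically realistic.

## Numerical and design notes

- Cycle length is a parameter (default 1 year); background mortality is
  converted per-cycle as `1−(1−q)^cycle_length`, other transition
  probabilities are interpreted per cycle.
- `days_in_hospital` and the itemised surgery costs are carried for
  completeness but the aggregate resection price drives the model; the
  tabulated aggregate ($21,592) differs from the itemised sum ($22,692)
  and is used as printed.
- Problem sizes: 13-cycle base case (< 10 ms), 50,000-iteration PSA
  (< 1 s vectorised), 100,000-patient oracle runs in the test suite.

## Limitations

- The four structural calibration choices are identifiability assumptions:
  other combinations (e.g. a different horizon with different recurrence
  costing) could fit the same reported numbers.
- PSA dispersions are calibrated, not estimated from primary data; the
  acceptability shares inherit that choice.
- No ablation comparators, no patient heterogeneity beyond age, no tunnel
  states beyond the single recurrence state, and no cost inflation over
  the horizon.
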