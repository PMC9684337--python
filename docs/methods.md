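# Methods

## Model structure

The model is a discrete-time Markov cohort model with four states —
remission, depression, mood episode ((hypo)mania), death — and a cycle
length of one quarter (0.25 years, 13 weeks). BD-I and BD-II are run as
two separate traces that share the model machinery but differ in
transition rows, the depression/mania time ratio, and the episode-state
utility; results are combined on the increment scale with prevalence
weights 0.600/0.400. The model has no memory: episode history does not
alter future transitions, and treatment discontinuation is not modeled.
The comparator is the standard of care; an intervention is an add-on
characterised by relative risks on episode entry and a cost stream.

## Transition probabilities

The packaged alive-state rows, per cycle, ordered (→remission,
→depression, →episode):

|            | BD-I                  | BD-II                 |
|------------|-----------------------|-----------------------|
| remission  | 0.880, 0.094, 0.026   | 0.880, 0.117, 0.003   |
| depression | 0.365, 0.561, 0.074   | 0.365, 0.561, 0.074   |
| episode    | 0.628, 0.074, 0.298   | 0.878, 0.074, 0.048   |

Residual entries (remaining in remission; returning to remission from a
mood state) are always recomputed as one minus the explicit exits, so the
matrices are row-stochastic by construction; exits summing above one raise
an infeasibility error naming the row.

The derivation calculus is exposed for re-parameterization:

- **Period conversion** assumes a constant hazard within the period:
  `1 − (1 − p)^f` (e.g. annual 21.9% → quarterly 5.99%). Implemented with
  `log1p`/`expm1`. The forward/backward round trip is exact to well below
  1e-12 as long as the intermediate probability is not pushed extremely
  close to 1; at (p = 0.99, f = 4) the intermediate is 1 − 1e-8 and a
  64-bit float can no longer carry the survival fraction below ~1e-11 —
  an inherent representation limit, irrelevant at the probabilities and
  period ratios the model uses.
- **Relative-risk calibration** converts both trial arms' 12-month
  recurrence probabilities to the cycle scale before taking the ratio:
  (68% vs 59%) and (48% vs 59%) yield the default RRs 0.81 and 1.32.
- **Relapse splitting** divides a total remission-exit probability between
  depression and the episode state in proportion to the depression/mania
  time ratio. The larger share is computed directly and the smaller by a
  Sterbenz-exact subtraction, so the parts sum to the total bit-exactly.
  Note the packaged literal rows are *not* the product of this split: the
  published row values embody an additional, unpublished calibration to
  observed mood-state prevalences, so they ship as literals and the split
  is used only to construct ratio scenarios (which hold each subtype's
  total remission-exit probability, 0.120, fixed).
- **Episode duration** is exponential time-to-recovery fitted to survival
  quantiles: one quantile gives the closed form −ln(S)/t, several give the
  least-squares slope of −ln(S) on t through the origin (unweighted; the
  original fitting software and quantile sets are not published, so the
  packaged stay probabilities are taken as authoritative rather than
  refitted).

## Mortality

The lifetable supplies the annual background death probability q(age);
ages beyond the table are treated as certain death, defining the terminal
age. Each cycle, q at the cohort's integer age (floor of start age plus
elapsed years) is converted to a rate, multiplied by the all-state
mortality rate ratio (2.06), combined with the suicide rate ratio (9.66)
in the depression state — multiplicatively on the rate scale by default;
an additive-on-rate alternative adds excess rates, i.e. multiplier
2.06 + (9.66 − 1) — and converted back for the quarter. Death is embedded
as a competing risk: the death entry is the state's cycle death
probability and all alive destinations are scaled by its complement.

The built-in synthetic lifetable uses a Gompertz–Makeham hazard
q(age) = 1 − exp(−(a + b·c^age)) with a = 5e-5, b = 3e-5, c = 1.094,
terminal age 110. These values give an implied life expectancy at birth of
about 82.5 years, resembling a modern Western European schedule; the
generator is a deterministic stand-in for national mortality statistics
and none of the headline epidemiology figures depend on it.

## Run settings and outcome accumulation

Defaults: start age 40, cohort starting 100% in remission (a
relapse-prevention population), lifetime horizon (to the lifetable's
terminal age; 280 cycles from age 40), alternatively any fixed number of
cycles (20 cycles = the 5-year horizon). Intervention relative risks apply
for cycles 0..effect_cycles−1; the default effect persists 4 cycles.

Life years, QALYs, and costs all use the same accrual rule: with
half-cycle correction (default on) the credited occupancy of cycle t is
the trapezoid mean of the occupancies at its start and end; discounting
multiplies cycle t by (1 + r)^(−t·cycle length) with annual rates r
(costs 4%, effects 1.5%; cycle 0 undiscounted). QALYs weight alive
occupancy by per-state utilities (remission 0.80, depression 0.29, mania
0.54; BD-II hypomania 0.80, equal to remission).

## Costs and perspectives

Per-state per-cycle cost inputs (2021 EUR) cover drugs, medical services,
psychological treatment, home-based treatment, indirect medical costs,
productivity losses, patient-and-family costs, and admissions. The
healthcare perspective excludes productivity and patient-and-family costs
(a strict subset of the societal perspective). Productivity losses are
zeroed from the first cycle whose start age reaches the retirement age
(67, integer-age granularity). The packaged per-state aggregates already
reflect the default treatment-intensity mix (85/15 outpatient low/high in
remission, 90/7/3 in depression, 30/40/30 outpatient-low/high/inpatient in
an episode); the `IntensityMix` type re-blends component-level unit costs
for users supplying their own. The intervention cost (€291/cycle for 1
cycle by default) is charged in the intervention arm across all alive
states; a remission-only scope is configurable since the evidence on its
state restriction is ambiguous.

## Incremental results

ΔC and ΔQ are computed on discounted totals. ΔQ > 0 with ΔC < 0 is
labelled dominant, ΔQ < 0 with ΔC > 0 dominated, otherwise the ICER
ΔC/ΔQ is reported; ΔQ = 0 yields no ratio. The weighted result weights
per-subtype increments first and forms the ratio afterwards.

## Probabilistic sensitivity analysis

Distribution families follow standard practice for each parameter class:
Dirichlet for transition rows (concentration = mean row × effective sample
size; structural zeros stay zero), beta for utilities (method of moments
from mean and SE), gamma for costs (mean and CV), lognormal
(median-preserving) for rate ratios, and beta-PERT for bounded inputs
such as session counts. The sources give families but no dispersion
magnitudes, so defaults are package choices, echoed into the PSA metadata
and fully overridable: transition ESS 100, cost CV 0.2, utility SE 0.05,
RR log-SD 0.1. A dispersion of zero (or an infinite ESS) degenerates that
block to its means, so a fully degenerate PSA reproduces the
deterministic result draw for draw. Because the dispersions are package
defaults, PSA summary numbers (e.g. the probability cost-effective at
€50,000) are conditional on them and are not treated as reproductions of
any published value.

Each iteration spawns one child seed from the root seed sequence, and
within an iteration one independent stream per parameter block
(transitions, utilities, costs, rate ratios), so adding a parameter to
one block never reshuffles another block's draws and seeded runs are
bit-reproducible. The CEAC reports, per willingness-to-pay λ, the
fraction of iterations with strictly positive net monetary benefit
λ·ΔQ − ΔC (ties count as not cost-effective). The default grid spans
0–200,000 € in 5,000 € steps plus the 3×GDP threshold €147,300.

## Numerical choices and degenerate inputs

- Stationary distributions solve πP = π, Σπ = 1 by least squares after a
  rank check that rejects reducible chains; the engine's long-run trace
  occupancies agree with the linear solve to 1e-6 after 10^4 cycles.
- Traces conserve probability mass to 1e-12 per cycle; death occupancy is
  nondecreasing.
- A null intervention (RRs 1, zero cost) produces bit-identical arms —
  residual recomputation uses the same floating-point expression in both
  code paths deliberately.
- Config loading deep-merges user YAML onto the packaged defaults;
  unknown keys raise, rows are validated to sum to 1 within 1e-9, and an
  empty config equals the defaults exactly.
- Monetary outputs are rounded (whole euros, probabilities to 4 d.p.)
  only at the reporting layer.

## What the tests do and do not show

The test suite exercises the model at the packaged parameterization and
with the synthetic lifetable. Passing tests demonstrate the calculus
(conversions, splits, fits), the engine's conservation and convergence
properties, the economics identities, and PSA reproducibility — under
the packaged Dutch-context inputs. They do not validate the packaged
parameter values against patient data beyond the built-in epidemiology
check (long-run weighted mood-state prevalences of 78% remission / 18.8%
depression / 4% (hypo)mania), and absolute QALY/cost totals depend on the
user's lifetable and start conditions. Published case-study totals that
depend on an unpublished national lifetable, start conditions, and PSA
dispersions are treated as qualitative context, not test targets. Test
problem sizes (20-cycle horizons for PSA and CLI checks, ≤10^4-cycle
power iterations, 10^5 distribution draws) were chosen to make the
properties sharp while keeping the suite fast.

## Known limitations

Markov lack of memory; fixed cycle length; single severity level per
mood state; no treatment discontinuation or compliance; no
budget-impact or multi-payer cost splitting; no expected-value-of-
information analysis. Generalizability of the packaged costs and the
standard-of-care mix is limited to health systems resembling the Dutch
context.
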