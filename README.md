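# bipolarce

A Markov cohort cost-utility model for evaluating pharmacological and
non-pharmacological interventions in bipolar disorder types I and II
(BD-I / BD-II), as a tested, config-driven Python library with a CLI.

## The problem and the model

Bipolar disorder is a recurrent mood disorder alternating between
depressive episodes, (hypo)manic episodes, and remission. Decision makers
weighing relapse-prevention interventions need long-term cost-per-QALY
evidence that single trials cannot provide. This package extrapolates
trial-scale effects over a lifetime with a four-state Markov cohort model:

- **States**: remission, depression, mood episode (mania for BD-I,
  hypomania for BD-II), and death (absorbing).
- **Cycle**: 3 months (13 weeks). Per-cycle transition probabilities
  among the alive states are row-stochastic 3×3 matrices per subtype,
  derived from published annual recurrence rates via the constant-hazard
  conversion `p_cycle = 1 − (1 − p_annual)^0.25`, episode-duration
  survival quantiles fitted as exponential time-to-recovery, and a
  depression/mania time ratio that splits relapse between the two mood
  states.
- **Mortality**: an age-dependent background death probability `q(age)`
  (from a `age,qx` CSV lifetable or a built-in Gompertz–Makeham
  generator), multiplied on the rate scale by a mortality rate ratio of
  2.06 in all alive states and an additional suicide rate ratio of 9.66 in
  depression, then embedded into the cycle matrix as a competing risk.
- **Interventions** are specified by relative risks on entering depression
  and the (hypo)manic state (applied for a configurable number of cycles)
  plus a per-cycle cost. The packaged default is a mindfulness-based
  cognitive therapy add-on: RR 0.81 (depression), RR 1.32 ((hypo)mania),
  €291 for one cycle, effect persisting 4 cycles.
- **Valuation**: per-state per-cycle costs in 2021 euros under a
  healthcare or societal perspective (the societal adds productivity
  losses, cut at retirement age 67, and patient-and-family costs);
  standard-gamble utilities 0.80 / 0.29 / 0.54 (hypomania in BD-II valued
  at 0.80). Outcomes use half-cycle correction and annual discounting
  (4% costs, 1.5% effects).
- **Results**: the two subtype traces (prevalence weights 0.600 / 0.400)
  yield incremental costs ΔC and QALYs ΔQ and the ICER ΔC/ΔQ — a ratio of
  weighted increments, never a weighted average of ICERs — with dominance
  labelling. A probabilistic sensitivity analysis (Dirichlet transition
  rows, beta utilities, gamma costs, lognormal rate ratios, beta-PERT for
  bounded inputs; 5,000 iterations by default) produces the
  cost-effectiveness plane and the CEAC under the net-monetary-benefit
  rule `λ·ΔQ − ΔC > 0`.

## Worked example

Run the default analysis (packaged parameters, built-in synthetic
lifetable, societal perspective, lifetime horizon from age 40):

```sh
$ bipolarce run --synthetic-lifetable --out demo-out
weighted delta costs (societal): EUR -534
weighted delta QALYs: 0.0247
result: dominant (ICER n/a)
```

The intervention arm gains 0.0247 discounted QALYs per patient
(prevalence-weighted across subtypes) while saving €534, so it *dominates*
the standard of care — better and cheaper — and no ICER is printed. Under
`--perspective healthcare` (which drops productivity and family costs) the
same comparison costs slightly more than it saves and yields a positive
ICER instead. `demo-out/` contains per-arm totals (`results.csv`),
increments (`summary.json`), the four cohort traces, an epidemiology
validation report, and a manifest with the config hash and seed.

The validation report checks the modeled disease course: the stationary
distributions of the two default alive-state chains, weighted 0.600/0.400,
put **78%** of live patients in remission, **18.8%** in depression, and
**4%** in a (hypo)manic episode.

A probabilistic sensitivity analysis:

```sh
$ bipolarce psa --synthetic-lifetable --n 200 --seed 1 --out demo-psa
probability cost-effective at EUR 50,000/QALY: 0.9200
```

i.e. 92% of the 200 sampled parameter sets give positive net monetary
benefit at a €50,000/QALY willingness-to-pay. The default 5,000 iterations
take a couple of minutes. Scenario analyses over alternative
depression/mania time ratios:

```sh
bipolarce scenario --synthetic-lifetable --ratios "6,14;3.6,38.7" --out scenarios.csv
```

All parameters can be overridden by a YAML config whose schema mirrors
`bipolarce.default_parameters().to_dict()` (see `save_parameters` for a
complete template); unknown keys are rejected to catch typos.

## Layout

- `src/bipolarce/parameters.py` — domain types, packaged defaults, config I/O
- `src/bipolarce/derivation.py` — probability calculus (period conversion,
  RR calibration, relapse splitting, exponential recovery, matrices,
  state-specific mortality)
- `src/bipolarce/lifetable.py` — lifetable I/O and the synthetic generator
- `src/bipolarce/engine.py` — cohort traces, stationary distributions,
  half-cycle correction, discounting
- `src/bipolarce/economics.py` — costing, ICER/dominance, subtype
  weighting, ratio scenarios
- `src/bipolarce/psa.py` — parameter sampling, PSA, CEAC
- `src/bipolarce/cli.py` — `bipolarce` command
- `docs/methods.md` — modeling assumptions and numerical choices
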