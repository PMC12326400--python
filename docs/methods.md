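# Methods

## Decision problem and perspective

`pdcea` compares seven device-aided strategies for advanced Parkinson's
disease from the Spanish National Health System perspective, in EUR
2023. Each strategy is a `TherapyScenario` in three parts: a care
pathway (pre-treatment work-up, procedure, follow-up resource use over
a 5-year costing horizon), a drug regimen priced at ex-factory (PVL)
level, and a Markov scenario producing discounted life-years and QALYs.
Only direct health-care costs are included; informal care and societal
costs are out of scope.

## Markov cohort model

The default state space has twelve states: {H&Y 2–3, H&Y 4, H&Y 5} ×
{low OFF (< 50% waking time), high OFF (≥ 50%)} on treatment, plus
surgical complication, PEG complication, adverse-event discontinuation,
switched, second-line therapy, and dead. The twelve-state count and its
ingredients (H&Y staging, OFF-time strata, complications, AE
discontinuation, switching, death) are fixed by the study design this
package operationalises; the exact enumeration is not published, so the
template is an explicit, configurable stand-in, loaded from YAML/JSON
(`states_12.yaml`). The dead state is unique, absorbing, with utility
and cost 0; utilities lie in [−0.5, 1].

The cohort starts with 50% of its mass in the high-OFF stratum (the
population starts device therapy when half the patients spend > 14 h/day
in OFF), split uniformly over the three H&Y bands. Propagation is
`x_{t+1} = x_t P` with row-stochastic `P` validated to 1e-9 and a
dead-absorbing row. Cycle length is 1 year by default (matching annual
discounting and the annual cost schedule) and configurable down to
monthly; no cycle length is prescribed by the source design, so the
coarsest consistent choice was taken.

**Discounting.** Effects are credited at the end of each cycle:
cycle *t* contributes `(1+r)^{-tΔ} · Δ` times the end-of-cycle alive
occupancy (life-years) or utility-weighted occupancy (QALYs), for
t = 1..T; the time-zero occupancy is excluded. The optional half-cycle
correction credits the mean of adjacent boundary occupancies at
discount time t − ½. Default r = 3.5%/year for costs and effects. The
effect horizon defaults to 20 annual cycles — deliberately longer than
the 5-year costing horizon, because the published discounted life-years
(6.385–8.151) exceed 5; at 3.5% the 20-cycle annuity bound is ≈ 14.21
discounted LY, comfortably above every target.

**Microsimulation.** `microsimulate` walks individuals through the same
chain with an explicit `numpy` Generator seed and accumulates the same
discounted sums, returning means with standard errors. It exists as a
stochastic oracle for the cohort engine (agreement within 3 SE at 10^5
walkers), not as an analysis tool.

## Costing

Pathway cost is Σ count × unit cost, computed in `Decimal` and rounded
to cents; annual drug cost is cost-per-standard-unit × units/day × 365,
rounded to whole euros (the printed precision of the source regimen
table). Discounted totals over the 5-year horizon place pre-treatment
and procedure items at t = 0 undiscounted, spread follow-up items
(classified per item in the unit-cost table's `phase` column) uniformly
over the horizon, and replicate the annual drug cost as an annuity-due
(start-of-year, Σ_{t=0..4}(1+r)^{-t} ≈ 4.6731), since treatment begins
immediately; end-of-year timing is available. Device replacement for
the DBS strategies is the single replacement listed in the resource
table — no extrapolated replacement cadence.

The published per-therapy *average annual costs* cannot be derived from
the stated inputs under any single discounting convention we examined;
the package therefore reports its own documented average
(discounted total / horizon) and never reproduces those figures.
Monetary parsing supports es_ES ("86.423,86") and en_US conventions
with structural validation of thousands grouping; all emitted CSVs are
dot-decimal regardless of input locale.

## Calibration of Markov scenarios

No transition probabilities are published for these therapies. The
generator builds a structured matrix over the default template —
forward H&Y progression (default 0.10/cycle), OFF-stratum drift
(0.05 each way), leakage to complication/AE/switch states (0.02 each),
severity-graded baseline death probabilities (0.025/0.045/0.085 for
H&Y 2–3/4/5; 0.05 for flagged states) — and calibrates two free
parameters per therapy:

1. a **mortality hazard multiplier** m scaling all baseline death
   probabilities (clipped at 1, survivor mass renormalised), solved by
   Brent's method so discounted LY hits the target; discounted LY is
   strictly decreasing in m, so the root is unique;
2. a **utility scale** k applied to all alive-state utilities;
   discounted QALYs are linear in k, so k = target/QALY(m, k=1) exactly.

The solver is deterministic and seed-free. Infeasible targets raise
with the binding bound: QALYs exceeding LY (utility cap 1), LY
exceeding the zero-mortality annuity bound, or a utility scale that
would push the maximum state utility above 1. Calibration tolerance
defaults to 1% relative (the targets carry four significant figures);
in practice the nested solve reproduces the targets to machine
precision, and a parameter-recovery round trip (simulate at known
(m, k), calibrate on the resulting effects) recovers both within 2%.

The flagged states allow no re-entry into on-treatment states (persist
or die); whether the original design allowed re-entry is unknown, and
with calibration anchored to aggregate LY/QALY totals the choice does
not affect any reported quantity.

Whether the published effect totals are discounted is not stated
explicitly; because the 3.5% rate is declared for "costs and utilities"
alike, calibration treats them as discounted at 3.5%. Printed without
decimal separators, the effect totals are read as thousandth-scaled
(6385 → 6.385 LY): life-years in the thousands are impossible, and the
monetary columns of the same tables use es-ES separators.

## Cost-utility analytics

ACE = C/LYG, ACU = C/QALY (exact division; ACE·LY = ACU·QALY = C within
1e-9 relative). ICER/ICUR = ΔC/ΔE with sentinels instead of ratios when
one option dominates or both coincide. The reference strategy for
incremental analysis is the lowest-ACU therapy (Dacepton on the
packaged data), configurable.

**Dominance** is available in two modes:

- `versus=<reference>`: a strategy is *dominated* when the comparator
  costs no more and yields no less (one strict; equal effect at higher
  cost counts as dominated). This is the mode in which the packaged
  data reproduce the published structure — Apo-Go, Percept PC and
  Percept RC dominated by Dacepton.
- `versus=None`: textbook analysis — pairwise strict dominance over the
  whole set, then iterative extended-dominance removal on the
  cost-sorted survivors (a strategy whose ICER versus its cheaper
  neighbour exceeds the next stepwise ICER is bypassed by a linear
  combination). Collinear points are kept (removal requires a strictly
  cheaper blend). On the packaged implied totals this mode additionally
  flags Lecigon (same QALYs as Duodopa, higher cost) and Duodopa
  (implied total marginally above Foslevodopa's): the published average
  ratios are rounded to whole euros, and the ±0.05% reconstruction
  error is larger than the Duodopa–Foslevodopa cost gap. The unit tests
  assert both behaviours.

The efficiency frontier orders nondominated strategies by effect with
stepwise ICERs (strictly increasing on data in general position) and is
verified against an exhaustive blend-enumeration oracle on random
instances. WTP classification compares the ACU — or the finite ICUR
versus the reference, when present — to the band (default
22,000 / 25,000 / 60,000 €/QALY); edge ties classify downward.

**Total-cost basis.** The published total costs per therapy are not
printed; they are reconstructed as ratio × effect ("implied" basis, the
default, on which the dominance and incremental results rest). The ACU-
and ACE-implied reconstructions disagree by ~0.03–0.1% (printed
rounding), so ratio cross-checks validate to 0.5% relative, not
exactly. The pipeline can instead run on this package's own discounted
costing ("computed" basis); those totals differ substantially for the
gel therapies because the published cost aggregation is not derivable.

## Synthetic scenarios and what the tests show

`generate_scenario` draws random dead-absorbing chains (Dirichlet rows
with a progression tilt, mortality scaled by `mortality_scale`, uniform
utilities within a range) reproducibly from a seed. These scenarios
exercise structural invariants — row-stochasticity, mass conservation
to 1e-9, monotone death occupancy, QALY ≤ LY for unit-capped utilities,
equality of the cohort engine with explicit matrix powers to 1e-12 and
with microsimulation within 3 SE. They emulate the *mechanics* of
disease-progression models, not the epidemiology of Parkinson's
disease: passing tests validates the engine and analytics, not the
clinical realism of any particular transition matrix, which for the
packaged analysis is pinned down only through the calibrated aggregate
effects.

## Numerical choices

- Row-stochasticity tolerance 1e-9; oracle equality 1e-12; Brent
  tolerances 1e-12 (xtol and rtol).
- Money in `Decimal` for parsing/rounding (half-up), floats elsewhere.
- Ratios kept unrounded internally; presentation rounds to whole euros
  (`report_tables`), bounded by 0.5 €.
- Seeds are explicit arguments everywhere randomness exists
  (microsimulation, scenario generation); no global RNG state.
- Problem sizes in the validation suite: matrix-power checks on ≤ 5-state
  chains; microsimulation at 10^5 walkers; 20 calibration round trips;
  200 random frontier instances (≤ 8 strategies); 1,000 random scenarios
  for conservation/bound checks.

## Known limitations

- Transition matrices are calibrated stand-ins matching only aggregate
  discounted LY/QALY; state-level occupancy paths are not identified.
- The costing horizon (5 years) and effect horizon (20 years) follow
  the source design's asymmetry; a common-horizon analysis would need
  assumptions the inputs do not support.
- No probabilistic sensitivity analysis or CEAC; the comparative inputs
  are point estimates.
- Currency is fixed at EUR 2023; conversion (e.g. 1 € = 1.0815 USD) is
  presentation-only and not applied to any computation.
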