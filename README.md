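# pdcea

Markov cohort cost-utility analysis of device-aided therapies for
advanced Parkinson's disease, from the perspective of the Spanish
National Health System (SNS).

When oral/transdermal therapy no longer controls motor fluctuations,
seven device-aided strategies compete: continuous subcutaneous
apomorphine infusion (Apo-Go, Dacepton), deep brain stimulation
(Percept PC and the rechargeable Percept RC), levodopa-carbidopa
intestinal gel (Duodopa), levodopa-carbidopa-entacapone intestinal gel
(Lecigon), and foslevodopa/foscarbidopa subcutaneous infusion.
`pdcea` prices each strategy (care-pathway resource use over 5 years at
2023 public unit costs, plus annual drug acquisition at ex-factory PVL
prices), attaches discounted effectiveness (life-years gained, LYG) and
utility (quality-adjusted life-years, QALYs) from a 12-state Markov
model, and runs the comparative economics. It is aimed at health
economists and HTA analysts who want the full pipeline — costing,
cohort model, calibration, incremental analysis — as reusable, tested
code.

## The model

**Markov cohort engine.** Twelve health states combine Hoehn & Yahr
severity bands (2–3, 4, 5) with the share of waking time in OFF
(< 50% / ≥ 50%), plus surgical and PEG complications, adverse-event
discontinuation, treatment switch, second-line therapy and death
(absorbing). The cohort starts with half its mass in the high-OFF
stratum and evolves by annual cycles, `x_{t+1} = x_t P`. Discounted
effects at annual rate *r* (default 3.5%, applied to costs and effects
alike) are

```
LY   = Σ_{t=1..T} (1+r)^{-t} · Δ · Σ_{s alive} x_t[s]
QALY = Σ_{t=1..T} (1+r)^{-t} · Δ · Σ_s x_t[s] · u_s
```

with cycle length Δ = 1 year and an optional half-cycle correction.
A seeded individual-level microsimulation of the same chain serves as a
stochastic cross-check of the cohort engine.

**Calibration.** Published transition probabilities do not exist for
these strategies, so per-therapy scenarios are calibrated: a mortality
hazard multiplier is solved (Brent's method; discounted LY is strictly
decreasing in it) so the cohort reproduces the therapy's discounted
life-years, then the utility vector is rescaled to reproduce its QALYs.

**Comparative economics.** Average ratios ACE = C/LYG and
ACU = C/QALY; incremental ratios ICER/ICUR = ΔC/ΔE; strict and extended
dominance; the efficiency frontier with stepwise ICERs; incremental
cost-utility plane coordinates; classification against a
willingness-to-pay band (22,000–25,000 €/QALY, up to 60,000 €/QALY in
special situations); optional net monetary benefit.

## Worked example

```python
from pdcea import CostUtilityAnalysis, load_advanced_pd

bundle = load_advanced_pd()                      # packaged 7-therapy tables
res = CostUtilityAnalysis(bundle.implied_total_costs()).fit()
print(res.summary())
```

```
Cost-utility analysis
---------------------
strategies:  7
reference:   dacepton (lowest ACU)
measure:     qalys
dominated:   apogo, percept_pc, percept_rc

 therapy_id  total_cost  life_years  qalys  ace_eur_per_ly  acu_eur_per_qaly    dominance icur_vs_reference                wtp_class
      apogo       79669       6.385  2.885           12478             27615    dominated         dominated above_band_below_special
   dacepton       59956       6.385  2.885            9390             20782 nondominated         reference              below_lower
 percept_pc       69647       6.495  2.800           10723             24874    dominated         dominated              within_band
 percept_rc       86332       6.495  2.800           13292             30833    dominated         dominated above_band_below_special
    duodopa      218116       7.055  3.120           30917             69909 nondominated           673,021            above_special
foslevodopa      217450       8.151  3.605           26678             60319 nondominated           218,742            above_special
    lecigon      324480       7.055  3.120           45993            104000 nondominated         1,125,634            above_special
```

Dacepton is the reference (lowest cost per QALY, 20,782 €/QALY). It
dominates Apo-Go (same QALYs, higher cost) and both DBS devices (fewer
QALYs, higher cost). Moving from Dacepton to any of the more effective
gel/infusion strategies costs between ~219,000 and ~1,126,000 € per
QALY gained — far above the willingness-to-pay band.

The same pipeline runs from a shell:

```bash
pdcea run --calibrate --plot --out results_dir   # costs, CEA table,
                                                 # frontier, CE plane,
                                                 # calibration, provenance
pdcea cea --fixture --markdown                   # the table above
pdcea calibrate --therapy dacepton               # Markov calibration
pdcea fixture --out tables/                      # export the input tables
```

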