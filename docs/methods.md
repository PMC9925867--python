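# Methods

This note records the model's assumptions, parameters, numerical choices
and the design decisions taken where the methodology was genuinely open.
It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Model structure

Three health states: *current smoker*, *former smoker*, *dead* (absorbing).
A cohort enters 100% current-smoker at a starting age between 12 and 100
and cycles annually until age 100 (the terminal age is
absorbing-by-death: the generated life table forces q = 1 there) or until
a configured shorter horizon.

**Cycle 0** is the intervention year: every member accrues one year of
current-smoker cost and utility plus the arm's per-participant
intervention cost, undiscounted. The arm's 12-month quit probability
materialises at the end of cycle 0 — the first transition — after which
the net cessation/relapse rates govern every later transition. This
places the intervention effect exactly at the 12-month boundary.

**Conditioning order.** Death competes first. With annual death
probability *d* (life table at the attained age/sex/status × SMI
mortality RR, capped at 1) and quit probability *q*, the current-smoker
row is [(1−d)(1−q), (1−d)q, d]. Rows are stochastic by construction; no
renormalisation is ever applied. This is the standard cohort-model
convention; the alternative (smoking transition first) differs only at
second order in d·q.

**Accrual.** Costs and QALYs accrue for the full year at start-of-cycle
occupancy; no half-cycle correction. Discounting is (1+r)^(−t) with
cycle 0 undiscounted and r = 3.5%/year for both costs and QALYs.

**Age indexing.** A cohort starting at age a is aged a+t during cycle t;
mortality, prevalence, costs and utilities are looked up at the attained
age.

## Parameters

All monetary values are GBP 2018/19. Per-arm 12-month quit probabilities
(mean, SD on the probability scale): bespoke intervention 0.173 (0.024),
usual care 0.119 (0.020), integrated care 0.089 (0.013), clinic referral
0.045 (0.010). Intervention costs per participant: £581 / £96 / £963 /
£412 (printed totals are canonical where they disagree with component
sums by a few pounds of source-table rounding; a ±£7 tolerance is
enforced at load time).

SMI-specific adjustments: relative mortality risk 2.22 (SD 0.02,
lognormal), comorbidity odds ratio 3.10 (SD 0.29, lognormal), SMI
disutility 0.125 (SD 0.013, beta). The disutility is the
population-weighted average of condition-specific decrements (mood
disorder 0.196 × 38.8%, anxiety disorder 0.043 × 51.6%, substance misuse
0.278 × 9.6% → 0.125); where source tables print the rounded 0.13, the
derived 0.125 is adopted as canonical.

Utilities: non-smoker base 0.88 (SD 0.13); decrements 0.04 current
smoker, 0.02 former smoker (SD 0.01 each). Comorbidity utilities and
annual costs: asthma 0.73 / £1,433, COPD 0.73 / £636, CHD 0.76 / £1,178,
lung cancer 0.61 / £10,772, MI 0.80 / £1,135, stroke 0.48 / £5,618.

**Utility combination** is additive: u = clamp(base − status decrement −
SMI disutility − Σ_c prev_c·(base − u_c), 0, 1). Comorbidity decrements
are summed with no multiplicative interaction (joint-prevalence data are
unavailable), and the SMI disutility subtracts rather than multiplies —
the source modelling framework does not pin this down, so the simplest
additive rule was chosen and is isolated in one function
(`cohort.state_utility`) should a different rule be needed.

**Comorbidity uplift.** The odds ratio is converted cellwise to a
relative risk, RR = OR/(1 − p + p·OR), and the adjusted prevalence is
min(1, p·RR) — algebraically the exposed-group risk implied by the odds
ratio, so it can never leave [0, 1]. Asthma is exempt (its exacerbation
rates match the general population) and the exemption travels with the
parameter table (`smi_adjustable` flag), not with code.

Transition rates after the first year: net cessation 2.0%/yr (SD 0.3%),
relapse 0% — the net rate already absorbs relapse at the population
level, so the base case is deliberately unidirectional.

## Synthetic reference surfaces

Three inputs the model needs are not shipped as real data and are
generated synthetically, with CSV import available for real data:

- **Life table**: Gompertz q(age) = a·e^(b·age) per sex, times smoking
  -status multipliers (current 2.0, former 1.3, never 1.0), clipped to
  [0, 1]. Defaults a = 8×10⁻⁶ (female) / 1.2×10⁻⁵ (male), b = 0.095.
- **Prevalence**: logistic-in-age per condition with a former-smoker
  attenuation factor in (0, 1] and a small sex factor (0.9/1.1);
  asymptotes 0.052 (lung cancer) to 0.39 (COPD), midpoints 37–77 years.
- **Population weights**: Gaussian age profile (mean 40, SD 22) over
  ages 12–100, split equally by sex, normalised to sum 1.

The generator seed jitters the shape parameters by a few percent so
reproducibility and invariance can be property-tested across seeds;
structure (monotonicity in age, status orderings) is preserved for every
seed and checked by `validate()` on each container.

The two-parameter Gompertz and logistic forms were chosen because they
guarantee the monotonicity invariants by construction. The default
values were calibrated once — and then frozen — so that population-
averaged lifetime discounted QALYs land near 11–12 per person and
lifetime comorbidity costs in the tens of thousands of pounds, i.e. the
order of magnitude of published lifetime cost-utility results for this
population. What the synthetic surfaces do **not** emulate: real
national life-table levels or cohort effects, sex- and
condition-specific epidemiology beyond the global factors above,
duration-of-abstinence effects on former-smoker risk, or correlation
between conditions. Results on these surfaces therefore support
*structural and directional* conclusions (signs of increments, ordering
of scenarios, sensitivity rankings), not reimbursement-grade point
estimates for real populations.

The scenario-1 self-reported effectiveness inputs are likewise synthetic
placeholders (shipped in `self_report_effectiveness_synthetic.csv`,
higher than the validated rates with a wider between-arm gap); replace
them with real values to use scenario 1 substantively. Scenario-2
service-utilisation add-ons (£7,903 / £8,667 / £18,091 / £18,941 per
arm) are derived from published scenario-total minus base-total
arithmetic and are therefore real inputs, not placeholders.

## Probabilistic sensitivity analysis

Distribution families follow the usual health-economics conventions:
lognormal for the mortality RR and comorbidity OR, beta for
probabilities and utilities, gamma for costs. Shape parameters come from
method-of-moments inversion — gamma k = m²/s², θ = s²/m; lognormal
σ² = ln(1 + s²/m²), μ = ln m − σ²/2; beta ν = m(1−m)/s² − 1, α = mν —
with SD 0 collapsing to a point mass and beta infeasibility
(s² ≥ m(1−m)) raising an error that names the parameter. Utility
*decrements* are sampled on their magnitude from a beta (support [0, 1])
and applied with negative sign, preserving the stated family while
respecting the sign of the printed value.

Each of the 3000 iterations draws every uncertain parameter
independently (no published correlation structure to honour), applies
shared draws (mortality RR, OR, utilities, costs, transition rates) to
both arms — common random numbers — and draws each arm's effectiveness
independently. Intervention costs have no published uncertainty and stay
fixed. The probabilistic ICER is the ratio of mean increments; the
probability of cost-effectiveness at threshold λ is the fraction of
iterations with λ·ΔQ − ΔC > 0, evaluated on a £0–£50,000 CEAC grid
(step £1,000) and at arbitrary λ through the same code path. The
iteration count is fixed at 3000 rather than adaptive; the iteration
table is exportable for convergence inspection.

The evaluation engine is vectorised over (iteration × starting age ×
sex), so a full 3000-iteration PSA of one comparison takes seconds; the
readable single-cohort implementation (`cohort.run_cohort`) is retained
and the suite asserts the two paths agree to ~1e-10.

## Deterministic sensitivity and scenarios

One-way DSA moves each parameter with a non-zero SD to mean ± 1.96·SD
(lognormal parameters move on the log scale: e^(μ±1.96σ)), clamped to
the parameter's valid range. Effectiveness is varied in its own arm
only; shared parameters move in both arms simultaneously. Tornado
entries are sorted by the width of the *net-monetary-benefit* swing
rather than the ICER swing, because an ICER range is undefined whenever
a bound produces a dominance label; on the north-east quadrant the two
orderings coincide.

Scenarios: (1) self-reported effectiveness swapped in; (2) 12-month
service-utilisation costs folded into the cycle-0 intervention cost;
(3) the net transition rates replaced by separate cessation 4.1%/yr and
relapse 10%/yr from the second year onwards (one source table prints
4.4% for the cessation rate; both are supported,
`ScenarioConfig.scenario3(cessation=...)`, with 0.041 the default as the
value stated in the accompanying text). A horizon option truncates any
scenario (e.g. 5 years).

## Economics edge cases

Dominance labelling: ΔC < 0 with ΔQ ≥ 0 (not both zero) is *dominant*;
ΔC ≥ 0 with ΔQ ≤ 0 (not both zero) is *dominated*; ΔC = ΔQ = 0 is
*equivalent*; otherwise an ICER is reported, tagged with its quadrant
because a bare ratio is sign-ambiguous when both increments are
negative. The cost-effective flag is defined as NMB > 0, which coincides
with "dominant or ICER ≤ threshold" everywhere except the
measure-zero boundary NMB = 0 (treated as not cost-effective). All
arithmetic runs on unrounded values; rounding (whole £, 2 d.p. QALYs)
happens only in the reporting layer.

## Problem sizes

The shipped configuration evaluates 89 starting ages × 2 sexes × up to
89 annual cycles per arm; a deterministic comparison takes ~50 ms and a
3000-iteration PSA a few seconds. The acceptance script runs both
comparisons' base case, scenario variants and PSAs in well under a
minute.

## Known limitations

- Average-cohort dynamics only; no individual trajectories, so
  time-since-quit effects (relapse hazard, mortality convergence toward
  never-smoker rates) are not representable.
- A single former-smoker mortality curve per age/sex regardless of
  abstinence duration.
- Only six comorbidities; wider benefits of cessation are excluded, so
  QALY gains are, if anything, conservative in structure.
- The never-smoker mortality series is generated for completeness but
  unused: the cohort never occupies a never-smoker state.
- Synthetic reference surfaces (see above) bound what the numbers mean.
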