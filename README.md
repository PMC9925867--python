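# smokece

A lifetime Markov cohort cost-utility model for **tailored smoking-cessation
interventions in people with severe mental illness (SMI)**, written for
health economists and epidemiological modellers who want a tested,
scriptable implementation of the standard UK decision-analytic workflow:
three-state cohort dynamics, SMI-specific epidemiology, QALY/cost
discounting, ICER economics, and probabilistic, deterministic and scenario
sensitivity analysis.

## The model

A closed cohort enters as **current smokers** and moves through three
health states — current smoker, former smoker, dead — in annual cycles
from its starting age to age 100. The intervention acts once: the
12-month biochemically validated quit probability of the evaluated arm
drives the first current→former transition. Thereafter a *net* annual
cessation rate of 2% (absorbing quitting, failed attempts and relapse at
the population level) applies, with relapse 0 in the base case. Death
competes first each cycle: with death probability *d* from an
age/sex/smoking-status life table scaled by the SMI relative mortality
risk (RR = 2.22), the current→former flow is (1−d)·q, keeping rows
stochastic.

SMI-specific epidemiology enters three ways:

- **Mortality**: age/sex/status death probabilities × RR 2.22, capped at 1.
- **Comorbidity**: general-population prevalence of six smoking-related
  conditions (asthma, COPD, CHD, lung cancer, MI, stroke) is uplifted by
  an odds ratio of 3.1 converted to a prevalence-specific relative risk,
  RR = OR / (1 − p + p·OR); asthma is exempt.
- **Utility**: state utility u = clamp(0.88 − status decrement − 0.125
  (the population-weighted SMI disutility) − Σ_c prev_c·(0.88 − u_c), 0, 1).

Costs are annual comorbidity treatment costs weighted by prevalence, plus
a one-off per-participant intervention cost at cycle 0 (GBP 2018/19).
Costs and QALYs are discounted at 3.5%/year, averaged over starting ages
12–100 and both sexes with population weights, and compared pairwise:
ΔC, ΔQ, ICER = ΔC/ΔQ (or a dominance label), and NMB = λ·ΔQ − ΔC at
λ = £20,000/QALY.

Two comparisons are built in: a bespoke smoking-cessation intervention
vs usual care (`bsci_vs_uc`, quit probabilities 17.3% vs 11.9%, costs
£581 vs £96) and integrated tobacco-cessation/mental-health care vs
referral to a smoking-cessation clinic (`ic_vs_scc`, 8.9% vs 4.5%,
£963 vs £412).

The external data surfaces the model consumes — the life table,
comorbidity prevalence, and population age weights — are **synthetic**:
generated in-package with the qualitative structure the model assumes
(mortality rising with age, current ≥ former ≥ never smoker; prevalence
rising with age, current ≥ former), calibrated once so lifetime
discounted QALYs land near the published order of magnitude. Real
reference data can be dropped in as long-format CSV without code
changes. See `docs/methods.md` for every modelling choice.

## Worked example

```python
import smokece as sc

model = sc.CostEffectivenessModel.from_defaults(reference_seed=0)
print(model.evaluate("bsci_vs_uc").summary())
```

```
bsci vs usual_care
        row  cost_intervention  cost_comorbidity  cost_total  qalys   icer
       bsci                581             27314       27895  11.65      -
 usual_care                 96             27541       27637  11.58      -
incremental                485              -227         258   0.07 £3,930
NMB at £20,000/QALY: £1,055  (cost-effective: True)
```

Reading the table: the tailored intervention costs £485 more per
participant than usual care, but higher quitting reduces lifetime
comorbidity treatment costs by £227, leaving a net £258 for 0.07 extra
discounted QALYs — £3,930 per QALY, well under the £20,000 threshold,
so the intervention is cost-effective (positive net monetary benefit).

```python
psa = model.run_psa("bsci_vs_uc", n_iterations=3000, seed=42)
print(psa.summary())
```

```
PSA (bsci_vs_uc): 3000 iterations, seed 42
mean ΔC £256 (SD £136); mean ΔQ 0.066 (SD 0.048)
probabilistic ICER £3,878/QALY
P(cost-effective at £20,000) = 84%
```

Scenario analyses (`ScenarioConfig.scenario1/2/3()`), one-way tornado
analysis (`model.run_dsa(...)`) and plots
(`smokece.plotting.plot_ce_plane`, `plot_ceac`) follow the same pattern.

The same workflow is available from the shell:

```bash
smokece evaluate --comparison bsci_vs_uc --scenario base --psa 3000 \
    --seed 42 --out results/
smokece generate-reference --seed 0 --out refs/
smokece dsa --comparison ic_vs_scc --out results/
```

Every output directory gets a `manifest.json` with the seeds, input-table
hashes and package version needed to reproduce it bit-for-bit.

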