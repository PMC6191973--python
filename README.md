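# maximindesign

Optimal and maximin planning of two-treatment clinical trials with three
candidate designs — parallel (A/B), extended parallel (AA/BB) and crossover
(AB/BA) — when research costs **and outcome variances may differ between the
treatments**.

## Who this is for

Trial statisticians planning a two-treatment study of a chronic condition
(where a crossover is feasible) who need to decide, *before* the intraclass
correlations are precisely known, which design delivers a target power at
the lowest cost, how to split subjects over the two sequences, and how many
subjects to recruit.

## The model and the criterion

Outcomes follow a heteroscedastic linear mixed model

```
y_ij = β0 + β_treat·treat_ij + β_time·time_ij + β_t×t·treat_ij·time_ij
       + u0_j + ε_ij,         u0_j ~ N(0, σ0²),
       ε_ij ~ N(0, σ_εA²) under A,   ε_ij ~ N(0, σ_εB²) under B,
```

so the total variances are σ_A² = σ0² + σ_εA² and σ_B² = σ0² + σ_εB², and
the intraclass correlations are ρ_A = σ0²/σ_A², ρ_B = σ0²/σ_B² (with
variance ratio φ = σ_A²/σ_B² = ρ_B/ρ_A).  Designs are compared by the
asymptotic variance of the ML estimator of β_treat (or of the
treatment-by-period interaction β_t×t) under a budget constraint built from
per-treatment costs c_A, c_B, a measurement cost c_t, subject costs c_sp
(one period) and c_s2p (two periods), and per-sequence costs c_ts.

For each design the package provides, in closed form:

* the **optimal allocation** n1/n2 over the two sequences and the resulting
  minimal variance per unit σ_y²/C (σ_y² = σ_A² + σ_B², C the net budget);
* the **maximin design** over a rectangle
  [ρ_A^L, ρ_A^U] × [ρ_B^L, ρ_B^U] of plausible ICCs: the ICC pair that
  maximizes the optimal variance, so that planning there guarantees the
  power everywhere in the rectangle — cross-checked internally against a
  brute-force grid search;
* **required sample sizes** from the normal-approximation power identity
  `Var(β̂) = (β/(z_{1−α/2}+z_{1−γ}))²` with β = ES·√(σ_y²/2), plus
  small-sample additive corrections for the exact t-tests used in analysis
  (+1/+2 per arm for pooled-variance t, +2…+4 for Welch);
* **Monte Carlo verification**: simulate trials under the mixed model,
  analyze with the design's exact t-test, and check the achieved power
  against a predictive interval.

A headline result: for the treatment-by-period interaction the maximin
AA/BB design is *always* at least as efficient as the maximin AB/BA design;
for the treatment effect the crossover dominates whenever treatment costs
are similar or small relative to subject costs and the ICCs are not tiny.

## Worked example

Planning a crossover trial of two bronchodilators in COPD with FEV1 as
outcome, a medium effect (ES = 0.5), 80% power at two-tailed α = 0.05,
budget = number of subjects, and ICC ranges [0.10, 0.70] × [0.30, 0.90]:

```python
import maximindesign as md

costs = md.CostStructure.subject_count()
rect = md.ICCRectangle(0.10, 0.70, 0.30, 0.90)
spec = md.PowerSpec(alpha=0.05, power=0.80, es=0.5)

plan = md.maximin_sample_size(md.DesignKind.CROSSOVER,
                              md.EffectOfInterest.TREATMENT,
                              spec, costs, rect)
print(plan.rho_star, plan.n_raw, plan.N, plan.n1)
```

prints

```
(0.1, 0.3) 53.37249... 56 28
```

the worst-case ICCs are the lower bounds (0.10, 0.30); 54 subjects satisfy
the normal-approximation identity there; adding one subject per sequence
for the pooled-variance t-test gives 56 in total, 28 per sequence.  Running
`python examples/02_maximin_design.py` additionally shows the crossover
needs only 48% of the AA/BB and 43% of the A/B subject requirement
(whole-percent maximin variance ratios).  The other scripts under `examples/`
cover optimal allocation, power simulation and cost-scenario sweeps; the
same functionality is available from the shell via the `maximindesign`
CLI (`maximin`, `grid`, `samplesize`, `simulate`, `power`, `scenario`
subcommands, each accepting `--config`).

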