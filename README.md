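# ctmarkov

Continuous-time Markov multistate models with covariates for
interval-censored panel data — built to scale to cohorts of tens of
thousands of subjects.

## The problem

In long-term observational studies — the motivating case is disability
progression in multiple sclerosis, measured on the ordinal EDSS scale at
clinic visits every 4–6 months — subjects move among a finite set of
states, can worsen *and* recover, and are seen only at visit times: the
exact moment of any transition is never observed.  The natural model is a
continuous-time Markov chain with generator `Q` (off-diagonal `q_ij` =
instantaneous `i → j` rate) and proportional covariate effects

    q_ij(z) = q0_ij · exp( Σ_r z_r β_ij,r ),

so `exp(β_ij,r)` is the hazard ratio of covariate `r` on that specific
transition.  Over a visit gap `τ` the transition probabilities are
`P(τ) = Exp(Qτ)`, and each consecutive visit pair contributes the
observed entry of that matrix exponential to the likelihood.

Fitting this model is expensive because the likelihood, its gradient, and
its Hessian all require matrix exponentials for every observation
interval.  `ctmarkov` makes it tractable with three ingredients:

* **exact derivatives from block matrix exponentials** — the derivative
  of `Exp(A)` in direction `E` is the upper-right block of
  `Exp([[A, E], [0, A]])`, and a nested version of the same trick yields
  exact second derivatives for Wald standard errors;
* **mini-batch stochastic gradient ascent** — updates
  `θ_{d+1} = θ_d + λ_{d+1}(M/|B|) Σ_{m∈B} ∂log L_m/∂θ` on random subject
  batches with a decaying schedule `λ_{d+1} = (d+1)^{−0.6}`, plus restart
  and initialization policies for the non-concave likelihood;
* **batched Padé exponentials** — a scaling-and-squaring Padé-13
  implementation that exponentiates whole stacks of interval generators
  at once, so one gradient step over ~10⁴ intervals takes tens of
  milliseconds.

It also provides an exact trajectory simulator, a Monte-Carlo harness for
operating characteristics (bias, variance, CI coverage, test rejection
rates), descriptive tools (empirical transition matrix, rare-transition
filtering, EDSS state collapsing), and a CLI.  See `docs/methods.md` for
the full model and the numerical choices.

## Worked example

Simulate a 3-state band model (adjacent moves only, baseline rate 0.5 per
year) with one covariate whose true effect is `β = 0.4` on every
transition, observed twice a year for 12 years, then fit and report
hazard ratios:

```python
import numpy as np
from ctmarkov import (
    FitConfig, ParameterSet, SimConfig, TransitionStructure,
    fit, hessian_pade, simulate_dataset, wald_report,
)
from ctmarkov.optimizer import suggested_lr_scale

struct = TransitionStructure.adjacent(3)
true = ParameterSet(struct, np.full(4, 0.5), np.full((4, 1), 0.4),
                    covariate_names=("relapse",))
data = simulate_dataset(SimConfig(M=300, params=true, t_max=12.0,
                                  dummy_interval=0.5, seed=7))

config = FitConfig(batch_size=75, lr_scale=100 * suggested_lr_scale(data),
                   max_iters=300, restarts=2, seed=1)
result = fit(data, config, structure=struct)

report = wald_report(hessian_pade(result.params, data), result.params)
print(report.table[["parameter", "estimate", "se", "lo", "hi"]].round(3))
print(report.hazard_ratios.round(3))
```

Output (M=300 subjects, 7200 observation intervals, log-likelihood
−4899.5):

```
         parameter  estimate    se     lo    hi
          q0[0->1]     0.507 0.024  0.462 0.556
beta[0->1,relapse]     0.292 0.166 -0.033 0.617
          q0[1->0]     0.507 0.024  0.462 0.556
beta[1->0,relapse]     0.486 0.164  0.164 0.807
          q0[1->2]     0.496 0.024  0.452 0.544
beta[1->2,relapse]     0.482 0.165  0.158 0.806
          q0[2->1]     0.500 0.024  0.455 0.549
beta[2->1,relapse]     0.217 0.166 -0.109 0.543

transition covariate  at_value    hr    lo    hi
      0->1   relapse       1.0 1.339 0.967 1.852
      1->0   relapse       1.0 1.625 1.178 2.241
      1->2   relapse       1.0 1.619 1.171 2.239
      2->1   relapse       1.0 1.242 0.897 1.722
```

Every baseline rate is recovered within a standard error of the true 0.5
(events per year), and each β interval covers the true 0.4: a unit
increase of the covariate multiplies the corresponding transition
intensity by `exp(β̂)` ≈ 1.2–1.6 here.

The same pipeline is available from the shell:

```
ctmarkov simulate --config sim.yaml --seed 7 --out panel.csv
ctmarkov fit      --data panel.csv --config fit.yaml --out fit.json
ctmarkov ci       --fit fit.json --data panel.csv --ci-method pade --out ci.csv
ctmarkov mc       --scenario scenario.yaml --seed 1 --out report.csv
```

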