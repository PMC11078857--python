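# plsched

Profile-likelihood driven optimisation of sparse sampling schedules for
PK-PD parameter identification.

## The problem

When fitting an ODE model to sparse, noisy measurements — the typical
situation in pharmacokinetic/pharmacodynamic studies, where every blood
draw has a cost — *when* you sample determines how well you can pin down
the model parameters.  Classical model-based design of experiments scores
candidate designs with Fisher-information criteria, which linearise the
model around a nominal parameter point and can misjudge designs for
nonlinear models.  Monte-Carlo alternatives capture the nonlinearity but
cost orders of magnitude more computation.

`plsched` implements a middle road: score a candidate schedule by the
profile-likelihood confidence intervals it would yield, compressed into one
scalar, and search schedule space with a simple elitist genetic algorithm.
It is aimed at modellers who want to either tighten parameter confidence at
a fixed number of samples, or cut the number of samples while keeping the
same confidence.

## The metric and the model

For each free parameter `θ_i`, the profile likelihood fixes `θ_i` along a
range of values, re-minimises the weighted sum of squared residuals
`ψ(θ) = Σ ((C(θ,t_i) − C_M,i)/σ_M,i)²` over the other parameters, and reads
off the pointwise confidence interval `[θ_i⁻, θ_i⁺]` where
`ψ − ψ(θ̂) < χ²(0.68, 1) ≈ 0.99`.  The design metric is

    PLB_crit = sqrt( Σ_i ((θ_i⁺ − θ_i⁻) / (2 θ̂_i))² ),

the root-sum-square of normalised half-widths; smaller is better, and any
non-finite interval (a practically non-identifiable parameter) maps to +∞.
Evaluated on noise-free data at nominal parameters, the metric is fully
deterministic — which is what makes it usable as a GA fitness.  A
Monte-Carlo counterpart (`QB_crit`, from 16/84% quantiles of refitted
parameter ensembles) is included as an independent comparator.

The demonstration model is a one-compartment dose-response system
`Ċ = −kC/(1+βC) + (U_N + U_x(t))/V` with a one-minute bolus at t = 60 min,
simulated by fixed-step Euler over 0–600 min.  Three parameter scenarios and
three estimation cases (2, 3, and 4 free parameters; β > 0 only in the
saturable 4-parameter case) are built in.  Schedules obey practical
constraints: a sample at t = 0, gaps > 5 min, and no samples in the five
minutes after the bolus.  The GA evolves 100 schedules per generation by
weighted cloning of the best performers plus Gaussian time jitter
(N(0, 16 min)), with the best schedule passed through untouched; a minimax
mode optimises the worst case across several parameter scenarios at once.

See `docs/methods.md` for the full model, numerics, and design choices.

## Worked example

```python
import numpy as np
import plsched as P

scen = P.scenario(1, 1)                     # 2-parameter case, scenario 1
uniform = P.uniform_schedule(10)
print("uniform PLB_crit :", round(P.plb_crit_noise_free(scen, uniform), 4))

cfg = P.GAConfig(scenarios=(scen,), n_s=10, n_generations=30, seed=0)
result = P.run(cfg)
print("optimised PLB_crit:", round(result.best_metric, 4))
print("optimised schedule:", np.round(result.best_schedule, 1))
```

prints

```
uniform PLB_crit : 0.1336
optimised PLB_crit: 0.0931
optimised schedule: [  0.   19.5  29.5  38.6 297.7 302.7 307.7 312.7 317.7 322.7]
```

a 30% drop in the uncertainty metric from the same number of samples: the
GA concentrates draws just after the bolus (where the decay rate is most
visible) and around the mid-decay region, instead of spreading them evenly.
The identifiability screen shows why the 4-parameter saturable case is
excluded from optimisation:

```python
report = P.identifiability_screen(P.scenario(3, 1), P.uniform_schedule(20))
print(report.passed)                        # False
ci = dict(zip(report.parameter_names, report.intervals))["beta"]
print(f"[{ci.lower:.2f}, {ci.upper:.2f}]")  # [-20.21, 44.69]
```

β's confidence interval reaches far below zero — physically infeasible for
saturable kinetics — so no schedule optimisation can rescue this case.

The same analyses are available from the shell:

```bash
plsched screen --case 3 --scenario 1 --ns 20
plsched optimize --case 1 --scenarios 1,2,3 --ns 12 --generations 150 --seed 0 --out runs/minimax12
plsched tradeoff --case 1 --policy single --seed 0 --out runs/tradeoff1.csv
plsched compare-metrics --case 1 --ns 5,10,15 --seed 0 --out runs/corr1.csv
```

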