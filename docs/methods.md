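# Methods

## Model

`plsched` works with a one-compartment dose-response model for an arbitrary
concentration C(t):

    dC/dt = -k * C / (1 + beta * C) + (U_N + U_x(t)) / V

with first-order decay rate `k` (1/min), endogenous production rate `U_N`
(amount/min), volume of distribution `V`, and saturation coefficient `beta`
(1/concentration).  With `beta = 0` elimination is linear; `beta > 0` gives
Michaelis-Menten style saturable elimination.  `U_x(t)` is an external bolus,
modelled as a constant rate of 4.0 applied for one minute starting at
t = 60 min — i.e. the bolus adds `4.0 * dt / V` to the concentration over a
single integration step.  The system starts at its pre-bolus equilibrium
`C0 = U_N / (k V - beta U_N)`; a parameter set with `k V - beta U_N <= 0` has
no physical equilibrium and is treated as infeasible (objective +inf).

Integration is fixed-step forward Euler with `dt = 1` min on a 0-600 min
horizon.  The fixed-step scheme is deliberate: every quantity downstream
(objective values, profile bounds, metrics) is then bit-for-bit reproducible.
Sampling times are continuous; a schedule time between grid nodes is
resolved by linear interpolation of the two adjacent node values.  We
deliberately do not offer an integer-minute snapping mode: the optimiser
explores continuous times, schedules can always be rounded afterwards (the
metric changes negligibly under sub-minute shifts away from the bolus
step), and a second constraint system for integer gaps would double the
repair logic for no analytical gain.

Three reference parameter scenarios (k, U_N, V) = (4e-3, 1e-2, 400),
(2e-3, 5e-3, 400), (1e-3, 2.5e-3, 400) represent a progression towards a
saturated biological response.  Three cases of rising complexity define the
estimation problem: Case 1 identifies {k, U_N} (beta = 0, V a priori),
Case 2 identifies {k, U_N, V} (beta = 0), Case 3 identifies all four
parameters with beta = 1.

### A note on the linear-case evaluation

For `beta = 0` the Euler recurrence is linear, so its node values admit a
closed form: the scheme sits exactly at its fixed point before the bolus,
and afterwards the deviation from `C0` contracts by `(1 - k dt)` per step.
The hot-path residual kernel evaluates this geometric form at the sampled
nodes only; it is an algebraic identity of the same discrete scheme (the
test suite checks agreement with the step-by-step loop at rounding level),
not a different integrator.  Case 3 always integrates the full loop.

## Estimation

The objective is the weighted sum of squared residuals

    psi(theta) = sum_i ((C(theta, t_i) - C_Mi) / sigma_Mi)^2,

the Gaussian negative-log-likelihood surrogate.  Identification minimises
psi with bounded trust-region least squares (`scipy.optimize.least_squares`,
step and optimality tolerances 1e-7, open lower bound 0 on every free
parameter, upper cap 1e4 times the start to stop runaway steps on flat
objectives).  The inner loops of profiling and Monte-Carlo analysis use a
compact Levenberg-Marquardt refitter compiled with numba — the same
objective, scaled coordinates `x = theta / theta_start`, finite-difference
Jacobian, projected lower bounds — because profiling a single genetic-
algorithm run requires hundreds of thousands of warm-started refits and
per-call overhead dominates otherwise.  The two optimisers are cross-checked
against each other in the test suite.

Measurement noise is additive, zero-mean, Gaussian.  The noise level is a
free knob of the study design; the default is a constant standard deviation
of 5% of the generating scenario's equilibrium concentration
(3.125e-4 for the linear scenarios), with a proportional-to-signal variant
available.  Two properties limit the influence of this choice: the
percent reduction of the design metric between two schedules is invariant to
the noise scale (profile widths scale linearly with sigma), and the
PLB-vs-QB comparison applies the same sigma to both metrics.

## Profile-likelihood confidence intervals and PLB_crit

Each free parameter theta_i is profiled by fixing it along a range of values
and re-minimising psi over the remaining free parameters, warm-starting each
refit from the neighbouring grid point.  The pointwise confidence region is

    { theta : psi(theta) - psi(theta_hat) < chi2(alpha, dof) },

with alpha = 0.68 and dof = 1 by default, so the threshold is
chi2_inv(0.68, 1) = 0.9889 (~0.99).  A parameter is practically identifiable
when both threshold crossings exist within the search range.  The design
metric is the root-sum-square of normalised interval half-widths

    PLB_crit = sqrt( sum_i ((theta_i+ - theta_i-) / (2 theta_hat_i))^2 ),

a coefficient-of-variation-style scalar that lets parameters of different
magnitudes contribute comparably.  Any non-finite bound maps the metric to
+inf rather than a large cap, so non-identifiable schedules rank strictly
last in the optimiser.

Design-time metric evaluation uses noise-free data generated at the
scenario's nominal parameters: the best estimate is then the truth,
psi(theta_hat) = 0, and the metric is fully deterministic — the property
that makes it usable as a GA fitness without run-to-run jitter.

Numerics (all configurable):

* Walk: initial step 1% of |theta_hat_i| per direction, grown by step
  doubling plus a quadratic extrapolation of the profile towards the
  threshold, so a bound is bracketed in a handful of refits even when the
  interval is wide.
* Crossing: refined by regula falsi between the bracketing points to
  |psi - threshold| < 1e-6 * threshold, which locates bounds far more
  precisely than interpolating a fixed-resolution curve.
* Range caps: 100x |theta_hat_i| upward; 0.01x theta_hat_i downward, except
  that beta may profile to negative values (down to theta_hat - 100x) so
  that physically infeasible intervals are detected and reported rather
  than masked; at most 200 points per direction.  Hitting a cap without a
  crossing flags the bound non-finite.
* A generic, callable-based walker (dense walk targeting ~threshold/10
  increments, linear interpolation at the crossing) exists alongside the
  compiled PK-specific path; it serves closed-form oracles (quadratic and
  linear-regression profiles) and diagnostic curves, and the two paths are
  cross-checked on PK fixtures.

The pre-optimisation identifiability screen profiles every free parameter
on noise-free data and reports per-parameter bounds with finiteness and
feasibility flags; passing requires all intervals finite and lower bounds
non-negative.  On the saturable Case 3 this screen fails: beta's lower
bound crosses below zero (scenario 1 even at N_s = 20), and k and U_N upper
bounds diverge for scenario 3 at small N_s — so schedule optimisation for
Case 3 is moot and the package only demonstrates the screen there.

## Monte-Carlo comparator

The Q-criterion is `sum_i (Q_{i,0.9} - Q_{i,0.1})^2` over refitted-parameter
ensembles from noisy replicate datasets; the normalised QB_crit variant uses
the 16th/84th quantiles (capturing 0.68, matching the profile threshold)
inside the same root-sum-square form as PLB_crit.  Quantiles are linear
interpolation between order statistics throughout.  Defaults: 500
replicates, refit starts jittered +-10% uniformly around the truth, failed
replicates excluded from quantiles with their count reported.  Each
replicate's noise and start derive deterministically from the ensemble seed.

The correlation study scores a seeded first-generation population of random
schedules with both metrics and reports per-(scenario, N_s) Pearson (and
Spearman) correlations.  Because QB_crit is a stochastic estimate, its
sampling noise attenuates the observed correlation at small replicate
counts; at 50 schedules x 200 replicates the minimum correlation over
settings sits a few hundredths below its large-replicate value (see the
test suite), converging upward as replicates increase.

## Genetic algorithm

Organisms are sampling schedules of fixed size N_s under practical
constraints: one sample pinned at t = 0; consecutive samples more than
5 min apart; the five minutes after the bolus — the interval (60, 65], with
t = 60 itself allowed as a pre-bolus draw — infeasible due to local mixing;
all samples within [0, 600] min.  Constraint violations are repaired by
shifting the offending time to the nearest valid location (ties towards
earlier times); the strict gap is enforced with a 1e-9 min margin.  When a
forward repair pass overruns the horizon the tail is packed back from
600 min.

One generation: evaluate PLB_crit per organism and scenario; keep each
organism's worst case across scenarios (minimax — with one scenario this is
plain minimisation); rank ascending with a stable sort; clone through the
rank map `ceil((j/14)^2)` (14 copies of the best, 5 of the second, ...,
rank 52 in the last slot — defined for the standard population of 100;
other sizes require an explicit table); mutate every organism except the
top-ranked one by sequentially adding N(0, 16 min) noise to each time after
t = 0, repairing after each perturbation.  The untouched elite plus
deterministic evaluation makes the best metric exactly monotone
non-increasing.  There is no crossover, by design — the reference procedure
is cloning plus mutation only.  Per-organism mutation streams derive from
(seed, generation, organism), so results are independent of evaluation
order and reproducible.

Defaults: 100 organisms; 150 generations for minimax runs and 100 for
single-scenario runs; convergence is in practice complete far earlier
(typically within ~40 generations the best schedule has settled).

## Experiment drivers

* Trade-off curves: for each N_s in a case's range (3-20, 4-20, 5-20 for
  cases 1-3), run the GA and compare against the time-uniform comparator
  (N_s equi-distant samples on [0, 600] inclusive, repaired for the
  exclusion window).  The reported percent reduction is
  `100 (uniform - optimised) / uniform`.  With the per-scenario policy the
  reduction is computed per (scenario, N_s) row; with minimax, on the
  worst-case metric.  Note the minimax compromise necessarily achieves a
  smaller worst-case reduction (~25% on average for Case 1) than the
  per-scenario optimisations (~30-33%), since one schedule must serve all
  three scenarios.
* Heatmap validation: ratio of optimised to uniform PLB_crit over a
  log-spaced 15x15 grid of (k, U_N) spanning 0.5x-2x the scenario values
  (V, beta at scenario values); ratios below 1 mean the optimised schedule
  wins at that parameter point.
* Convergence report: per-generation best/median metrics and the first
  generation from which the best schedule stops changing.

Every driver is a pure function of (configuration, seed); rerunning
produces identical tables.

## What the synthetic data does and does not emulate

All data are simulated from the model itself with additive Gaussian noise:
there is no model mismatch, no heteroscedasticity beyond the optional
proportional mode, no missingness, and no inter-individual variability.
Passing tests therefore demonstrate the internal consistency of the design
machinery — that the metric ranks schedules as its definition implies and
that the optimiser improves it — not that an optimised schedule is robust
to structural error in a real assay.  Clustered sampling points chosen
under a wrong model can mask exactly such mismatch; the identifiability
screen is a necessary, not sufficient, safeguard.

## Problem sizes used in the shipped analyses

The acceptance driver enumerates the cloning rule exactly; runs the
correlation study at 50 schedules x 200 replicates per (scenario, N_s)
setting (N_s in {5,10,15} / {6,10,15} for cases 1/2); and runs the
per-scenario GA at 100 organisms x 100 generations across each case's full
N_s range.  These sizes reproduce the qualitative and quantitative findings
while keeping a full run in the minutes range on one core; the GA
generation count matches the reference single-scenario setting, and the
correlation study's replicate count is the main lever on how close the
observed minimum correlation sits to its asymptote.

## Known limitations

* The cloning table is hard-wired to populations of 100.
* Profile bounds assume a unimodal profile between theta_hat and the first
  threshold crossing; a profile that dips again beyond the crossing would
  be reported by its first crossing only.
* The Euler scheme with dt = 1 min is part of the model definition here;
  halving dt shifts trajectories by <0.5%, but profile bounds are defined
  against the dt = 1 scheme.
* Case 3 optimisation is deliberately not exposed as a headline driver
  because the identifiability screen fails there.
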