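# Methods

## Model

`ctmarkov` fits continuous-time Markov multistate models (CTMMs) to panel
data: subjects move among a finite set of states `S = {0, …, S−1}`, but are
observed only at visit times, so the exact transition times are interval
censored.  The process is governed by a generator matrix `Q` whose
off-diagonal entry `q_ij` is the instantaneous `i → j` rate; rows sum to
zero.  Covariates act multiplicatively (proportional intensities):

    q_ij(z) = q0_ij · exp( Σ_r z_r β_ij,r )

`q0_ij` is the baseline intensity at the covariate reference (covariates
should be centered so the baseline is interpretable at the mean), and
`exp(z_r β_ij,r)` is the hazard ratio of covariate `r` on that transition.
A transition-independent variant shares one `β_r` across all transitions.
Intensities are assumed time-homogeneous, and covariate values are carried
forward from each visit: the covariates recorded at the start of an
interval govern the intensities over that whole interval.  The likelihood
of one subject is the product over consecutive visits of

    ( Exp(Q_k · τ_k) )[s_{k−1}, s_k],    τ_k = t_k − t_{k−1},

the observed entry of the matrix exponential of the interval generator.
Transitions not listed in the model's `TransitionStructure` are structural
zeros and carry no parameters.

## Exact derivatives via block matrix exponentials

All derivatives are exact, not numeric.  The directional (Fréchet)
derivative of the matrix exponential is read off one block exponential:

    ∂Exp(A)[E] = upper-right block of Exp([[A, E], [0, A]])

Nesting the construction once more gives second directional derivatives
(a `4S × 4S` block exponential), including the curvature term `∂²A` when
the base matrix depends nonlinearly on the parameters.

Two computational reorganizations keep large panels affordable; both are
algebraic identities of the same construction and are tested to agree with
the direct per-parameter route at ~1e−14:

* **adjoint gradient** — the gradient of a single observed entry
  `P[s, s′]` with respect to *every* entry of `A` is one Fréchet
  derivative at `Aᵀ` in the rank-one direction `e_s e_{s′}ᵀ`; the chain
  rule to the parameters is then a gather, so the score costs one
  `2S × 2S` exponential per interval regardless of the parameter count;
* **ordered-integral Hessian** — every parameter direction is a scalar
  multiple of a per-transition base matrix `D_t` (`+1` at `(i, j)`, `−1`
  at `(i, i)`), and for a fixed first direction one `3S × 3S` block
  exponential yields the bilinear second-derivative functional against
  *all* second directions, so the Hessian costs `T` (number of modelled
  transitions) block exponentials per interval rather than one per
  parameter pair.

The matrix exponential itself is an own batched implementation of
scaling-and-squaring with the diagonal Padé-13 approximant, operating on
stacks `(n, S, S)` with a shared scaling exponent; it is validated against
`scipy.linalg.expm` to ~1e−14 on random generators.  The batched form is
what makes panel evaluation fast — ~10⁴ small exponentials per gradient
step execute as a handful of batched matmuls and one batched solve.
Intervals sharing `(τ, from, to, z)` are collapsed to unique rows before
exponentiation; with time-varying covariates this is a no-op, without them
it collapses whole datasets to a few dozen distinct rows.

## Estimation

The log-likelihood is maximized by mini-batch stochastic gradient ascent:

    θ_{d+1} = θ_d + λ_{d+1} · (M/|B_d|) · Σ_{m∈B_d} ∂log L_m/∂θ

with subject mini-batches `B_d` (shuffled epochs without replacement by
default) and learning rate `λ_{d+1} = lr_scale · (d+1)^{−0.6}`.  The
likelihood is not globally concave, so the fit runs multiple restarts from
random initializations and keeps the restart with the best full-data
log-likelihood.

Numerical choices, and why:

* **log-q0 scale.**  Optimization runs on `log q0` (betas unchanged), so
  baseline intensities stay positive under any step.  Reports transform
  back to the natural scale by the delta method; baseline-rate confidence
  limits are exponentiated log-scale limits.
* **learning-rate scale.**  The summed batch gradient grows with the
  number of observation intervals, so `lr_scale` of order
  `100 / n_intervals` (`suggested_lr_scale` times 100) keeps the first
  steps of order one; this was calibrated once against a deterministic
  quasi-Newton reference (criterion: log-likelihood gap and parameter
  error well under one standard error within 300 iterations) and is the
  default used by the Monte-Carlo harness and the CLI.
* **step cap.**  A single update is capped at sup-norm 1 (direction
  preserved).  One unit of log-intensity is far beyond any sensible move;
  the cap stops a noisy early mini-batch from throwing the iterate into a
  flat degenerate region that restarts would otherwise have to absorb.
* **non-finite guard.**  A batch producing a non-finite gradient (an
  observed transition with probability at the 1e−300 floor) triggers up
  to five learning-rate halvings, then the batch is skipped.
* **convergence.**  The stopping rule averages the sup-norm parameter
  change over the trailing five steps (raw SGD steps oscillate and would
  stop a literal per-step rule prematurely); default tolerance 1e−6,
  iteration budget `max_iters`.
* **initialization.**  `distance_decay_normal` draws `q0_ij` from the
  positive part of `Normal(1/|i−j|, 1/|i−j|)` — nearby states start
  faster — and betas from `Uniform(−1, 1)`; `warmstart_subsample` runs a
  deterministic full-gradient fit on a subject subsample and seeds the
  restarts with its optimum.
* **restarts.**  `FitConfig` defaults to 1000 restarts, appropriate for
  large ill-conditioned problems; the Monte-Carlo harness uses 20 by
  default and the shipped small scenarios use 2, which pilot runs showed
  already reach the quasi-Newton optimum on well-identified band models.

## Confidence intervals

Standard errors come from the observed information `−H` at the estimate.
Two Hessians are available:

* **`pade`** (default) — exact second derivatives via the nested block
  construction above;
* **`power_series`** — the likelihood entry is replaced by the truncated
  series `I + Qτ + ½(Qτ)²` and the truncated log-likelihood is
  differentiated twice analytically (no exponentials at all; attractive
  when `S` is large).  Intervals whose truncated entry is not positive are
  excluded and counted.

The truncation error of the power-series Hessian is `O(‖Qτ‖³)` (halving τ
shrinks the discrepancy ~8×, which the tests verify).  A caution from our
own measurements: on fitted toys at `‖Qτ‖ ≈ 0.2` the truncated curvature
is *smaller* in magnitude than the exact one (stay intervals dominate the
information, and their truncated log-entry is flatter), so power-series
standard errors come out ~8–15 % **wider** than Padé ones, not narrower.
The acceptance report measures this ordering rather than assuming it.

Wald reports give, per parameter: estimate, SE, 95 % interval, z, and a
5 %-level rejection flag; per (transition, covariate): the hazard ratio
`exp(z_r β̂_ij,r)` with the exp-transformed interval, evaluated at
`z_r = 1` or a user-supplied covariate value (centering offsets are stored
in the fit artifact so "at the mean" is reproducible).

## Synthetic data

The simulator emulates a long observational study of a disability score
(the EDSS-like setting that motivates the package): subjects followed up
to `t_max = 15` time units (years), assessed on a fixed schedule every
`dummy_interval` units (default 1/3, the 4–6-monthly clinical cadence;
the shipped scenarios use 1/2), covariates uniform on `(−1/2, 1/2)`
(centered), redrawn at every visit, with optional per-subject fixed
covariates.  The latent chain is simulated exactly (Gillespie): initial
state from the stationary distribution of the subject's initial generator,
exponential sojourns at rate `−q_ss`, next state from the embedded jump
chain `q_sj/(−q_ss)` (a `transition_probability` variant draws the
destination from the `Exp(Qτ)` row instead).  Because covariates change
only at visits, intensities are piecewise constant between visits —
exactly the carry-forward assumption the likelihood makes, so the
generator and the likelihood describe the same process.

**What is deliberately not emulated.**  Real cohorts have informative
visit timing (extra assessments when something happens), misclassified
states, dropout, and covariate processes with memory.  The default panel
is observed on the *non-informative* schedule only.  The flag
`observe_jumps=True` additionally emits a visit at each exact transition
time; we measured that fitting such data inflates the estimated
intensities by ~40 % at `qΔ ≈ 0.25` — visit times that coincide with
events violate the panel likelihood's premise.  Passing tests on the
default generator therefore demonstrates correctness of the estimator
under non-informative observation, not robustness to informative
sampling, misclassification, or dropout.

## Monte-Carlo harness

`run_scenario` simulates, fits, and scores replicates against the truth,
reporting per-parameter bias (mean of estimate − truth, natural scale),
across-replicate variance, 95 % CI coverage, and the 5 % Wald rejection
rate (type-I error under a null, power otherwise).  Aggregation over a
parameter class uses the mean of |bias| so opposite signs cannot cancel.
Coverage for baseline rates is evaluated on the log scale, which is
equivalent to the exponentiated interval containing the true rate.
Failed replicates are counted and excluded with a warning.  Replicates
use seed streams spawned from the scenario seed, so results do not depend
on execution order.  The realized observation count is recorded rather
than targeted — the visit schedule, not a quota, determines it.

The default truth is a band (tridiagonal) generator with
`q0 = 0.5 / |i−j|` and a common `true_beta` on every modelled
coefficient.  The shipped "smoke" scenario — `M = 200`, `S = 4`, `R = 2`,
`β = 0`, 50 replicates, 2 restarts of 300 iterations with batch 50 —
runs in roughly 5 minutes on one CPU and gives β coverage ≈ 0.95 and null
rejection ≈ 0.05; the full-scale configuration (`M = 500`, `S = 8`,
`R = 10`, hundreds of replicates, 20+ restarts) uses the same code path
via `ScenarioSpec`/`ctmarkov mc` and is sized in hours, not minutes.

## Known limitations

* Time-homogeneous intensities; no hidden/misclassified states; no
  event-time (exact transition) likelihood contributions.
* The SGD schedule has no momentum or per-coordinate adaptation by
  design; badly scaled problems rely on restarts and the step cap.
* The power-series Hessian is a large-`S` convenience with a documented
  bias direction on our toys (wider SEs); the Padé Hessian is the
  reference.
* `stationary_distribution` on reducible chains returns the law on one
  recurrent class with a warning; simulation from such models starts all
  subjects in that class.
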