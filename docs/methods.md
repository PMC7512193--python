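# Methods

## Model and assumptions

The package models decision-making as relaxation of a probability
distribution over actions toward a Boltzmann-like equilibrium
`p_eq(x|t) ∝ p0(x) e^{β U(x,t)}`, driven by an externally controlled
sequence of utility functions (the protocol).  Standing assumptions,
shared by all modules:

* the driving is exogenous — actions never influence how the utility
  changes;
* the precision `β` is constant along a protocol (the isothermal case);
* forward processes start in equilibrium at the first epoch, and reversed
  processes start in equilibrium at the last one — both fluctuation
  identities require this;
* deliberation kernels satisfy detailed balance with respect to their
  epoch's equilibrium.  `trajectory_ledger` measures the residual and
  records a warning above 1e−9, since the identities are then void.

Utility units are arbitrary: only the product `β·U` enters any
probability, so `β` carries inverse-utility units and `β U` is treated as
dimensionless throughout.

## Trajectory accounting and reversal conventions

For a trajectory `x = (x_0, …, x_N)` the work analog is the utility change
collected while an action is held, and the deliberation cost is the
stochastic-entropy difference `log p(x_n|x_{n−1}, t_n) − log
p(x_n|x_{n−1}, t_{n−1})`, charged at `1/β`.  Equilibria are taken relative
to a general prior `p0`; the prior log-weights telescope out of the
forward/backward ratio, so the Crooks and Jarzynski identities hold in
this generalized form with `ΔF = (1/β) log(Z_N/Z_0)`,
`Z_t = Σ_x p0(x) e^{β U(x,t)}`.  The epoch-0 conditional in the
deliberation regime is the equilibrium policy at `t_0` regardless of the
conditioning action — the device that makes the telescoping exact.

The backward measure reverses each forward transition through detailed
balance.  The epoch whose kernel performs the reversal follows from the
step ordering of the regime:

* *deliberation* — the move at step `n` happens under the new utility and
  the gain is evaluated after it; the conjugate reversal uses the kernel
  at `t_{n−1}`;
* *no-deliberation* — the gain is evaluated at the held action before the
  relaxation, which happens under the new utility; the conjugate reversal
  uses the kernel at `t_n`.

Each convention makes its Crooks identity exact for every trajectory; the
enumeration oracles in the test-suite check this to 1e−10 on random
instances, and both backward measures are verified to normalize to one.

Two path-probability conventions coexist and are never mixed: the exact
kernel measure (rejections folded into the diagonal; used in all theorem
oracles) and the accepted-move product (initial density × proposal ×
acceptance over accepted moves only; used to score continuous adaptation
trajectories in the hysteresis experiment).  The accepted-move product is
not the full chain measure — it omits rejection events — and is kept as a
separate scoring convention rather than reconciled with the kernel
measure.

Numerical choices: all probability arithmetic is in log domain
(log-sum-exp), since `β` up to 22.5 with quadratic utilities overflows
linear-domain exponentials; `β = 0` is an explicit limit branch returning
the prior and the prior-expected utility; Jarzynski averaging shifts by
the maximum of `β U_net` before exponentiating; exhaustive enumeration is
capped at 10^6 paths; ties in the `β → ∞` argmax split mass evenly
(symmetry of the Boltzmann weights); uncertainty bands use plain sample
variance, no bootstrap.

## Samplers

Rejection sampling with aspiration level `T ≥ max ΔU` accepts a prior draw
with probability `e^{β(ΔU−T)}`; the accepted action follows the
equilibrium policy exactly for any valid `T`, at expected cost
`e^{βT}/Z_β ≥ e^{KL(p_eq‖p0)}` draws.  The interrupted (anytime) sampler
emits a fresh prior draw when its budget `k` is exhausted; this emission
rule is what makes the mixture law
`(1−q_k) p_eq + q_k p0`, `q_k = (1 − Z_β e^{−βT})^k`, exact.  The discrete
Metropolis–Hastings kernel proposes from the prior and folds the rejection
mass into the diagonal, giving a proper stochastic matrix in detailed
balance with the equilibrium policy; the continuous variant uses a
symmetric Gaussian random walk (default burn-in 10^3 where histograms are
compared, no thinning).  All stochastic operations take an explicit
seed/generator; identical seeds give identical trajectories.

## Bayesian inference as a one-step-lag process

With the log-likelihood as utility, the free-energy-optimal update is the
tempered posterior `p0(θ) p(D|θ)^β / Z` — Bayes' rule at `β = 1`.  The
batch-size experiment is computed entirely in closed form for the
known-variance Gaussian case: conjugate updates, per-batch surprise as a
Gaussian cross-entropy, evidence via the one-step-ahead predictive chain
(hence exactly batch-partition invariant), and dissipation as a sum of
Gaussian Kullback–Leibler divergences.  The first law `ΔF + S = U_diss`
then holds batch by batch as an algebraic identity, which the tests check
to 1e−10.  The synthetic stream is 100 draws from N(5, 4); the belief
prior defaults to N(0, 10²), a broad choice on the data scale — the
qualitative claims (constant `ΔF`, first law, dissipation monotone in the
number of chunks) hold for any proper prior, and no absolute curve values
are asserted.  The general-`β` tempered update is implemented for discrete
hypothesis spaces; the Gaussian reproduction path fixes `β = 1`.

## Langevin deliberation

Continuous deliberation follows `dx/dt = α U′(x) + α ξ`, `⟨ξξ′⟩ = 2D δ`.
For concave quadratic utilities this is an Ornstein–Uhlenbeck process with
rate `c = 2αa`: the time-dependent Gaussian law, the finite-time
transition kernel and the stationary law are all closed-form.  Matching
the stationary Fokker–Planck solution `p_∞ ∝ exp(U/(αD))` to the
Boltzmann-Gibbs form fixes the effective precision `β_eff = 1/(αD)`; the
alternative product form `2αD` circulating in the literature is
inconsistent with that solution (and with "less noise, more precision")
and is reported in experiment logs but never used.  The closed-form
variance prefactor is derived from the first- and second-moment ODEs of
the Fokker–Planck equation and unit-tested against numerical ODE
integration and Euler–Maruyama simulation.

Net utilities and Jarzynski estimates use the *exact* transition kernels
rather than the marginal laws: the trajectory of a deliberating diffusion
is Markov across epochs, and only the conditional form satisfies the
fluctuation identities exactly at finite deliberation time.  The initial
strategy N(μ0, σ0²) is treated as the equilibrium of the implicit
quadratic utility `U_0(x) = −x²/(2β) + …`, meeting the equilibrium-start
requirement.  The printed experiment utilities are read in the concave
convention `U(x) = −(a x² + b x) + offset` (a₁ = 0.2, b₁ = −0.4, offset
−0.8; a₂ = 0.4, b₂ = −1.8, offset +1.025) so that equilibria normalize;
offsets cancel in every Δ-quantity and are carried only for plotting
absolute utility curves.  The integrator's default step obeys
`c·Δt ≤ 0.01`; a step at or beyond the stability limit `1/c` warns.

## Experiments and the synthetic data they emulate

* *bayes-batches* emulates a learner absorbing an i.i.d. Gaussian stream
  in chunks of size {100, 50, 25, 20, 10, 5, 2, 1}.
* *hysteresis* emulates a sensorimotor adaptation task: a quadratic error
  utility whose target moves 0 → 1, either in one trial or in 23 equal
  sub-steps, adapted to by Metropolis–Hastings with β = 22.5 and proposal
  spread 0.1 over 80 trials, with the switch at trial 40.  The
  free-energy difference vanishes (equal curvatures), so per-run
  dissipation is minus the collected utility gain.  Reversed-protocol
  runs re-simulate under the reversed schedule from the final
  equilibrium.  The number of repetitions is configurable (default 200).
* *episodic* emulates an 8-option brightest-light choice task with a
  uniform prior and two episodes.  The two utility vectors are this
  package's own defaults (the reference task specifies them only as a
  figure), so every check on this task is invariant-based: net utility
  monotone in the budget `k` (checked on the closed-form mean, which is
  exactly monotone because the mixture moves along a segment toward the
  maximizer of a concave functional), `ΔF` invariant in `k`, dissipation
  maximal at high `β` and low `k`.
* *langevin* runs the two-utility continuous task over (β, k) grids with
  `D = 1/(αβ)` per grid β; common random numbers are shared across the
  `k` grid so budget curves are smooth.

Problem sizes used by the default test run and the acceptance checks —
10^5 repetitions for sampler exactness, 10^4 Monte-Carlo trajectories for
the sampled Jarzynski and second-law bands, 2–5·10^4 particles for
Euler–Maruyama moment checks, 200 repetitions per hysteresis protocol —
are this package's choices balancing statistical resolution (3–4σ bands)
against run time.

## What passing tests do and do not show

The synthetic generators produce exactly the idealized conditions the
theory assumes: externally driven utilities, equilibrium starts, detailed
balanced kernels, i.i.d. observations.  Passing tests therefore establish
the correctness of the implementation and the internal consistency of the
identities; they do not establish that human or animal adaptation data
satisfy them — real data bring non-stationary priors, action-dependent
environments and model mismatch, all outside this package's scope (as are
bidirectional estimators such as Bennett's acceptance ratio, β-varying
protocols, adaptive proposal tuning, and utility learning).

## Known limitations

* Enumeration oracles are exponential in trajectory length; beyond the
  10^6-path cap only Monte-Carlo checks are available.
* The accepted-move path score of continuous chains is a convention, not
  a normalized path measure; quantitative per-trajectory Crooks checks in
  the continuous hysteresis setting are therefore not attempted.
* The episodic task's utility vectors being package defaults, its outputs
  are not comparable in absolute value to any external reference.
* Exponential-average (Jarzynski) estimators are heavy-tailed at large
  `β·U_diss`; standard errors can understate the true uncertainty in that
  regime, which the default grids avoid.
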