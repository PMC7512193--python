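"""Bounded-rational decision mechanisms: rejection sampling and Metropolis-Hastings.

Two sampling schemes realize the Boltzmann-like equilibrium policy without
ever computing its partition sum:

* rejection sampling with an aspiration level ``T >= max dU``: draw from the
  prior, accept with probability ``exp(beta (dU(x) - T))``.  The accepted
  action is distributed exactly as the equilibrium policy, at an expected
  cost of ``exp(beta T) / Z_beta`` prior draws per decision;
* Metropolis-Hastings: propose from the prior (discrete independence
  sampler) or from a Gaussian random walk (continuous state), accept uphill
  moves with certainty and downhill moves with probability
  ``exp(beta (U(x') - U(x)))``.  The chain satisfies detailed balance with
  respect to the equilibrium policy.

Interrupting either scheme after a finite budget ``k`` yields a
non-equilibrium policy; for rejection sampling it is the exact mixture
``(1 - q_k) p_eq + q_k p0`` with ``q_k = (1 - Z_beta exp(-beta T))^k``
(the residual probability that no draw was accepted, in which case a fresh
prior draw is emitted).

Every stochastic operation takes an explicit ``numpy`` Generator (or seed);
identical seeds give identical trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .policy import (
    ActionSpace,
    Policy,
    QuadraticUtility,
    UtilityEpoch,
    equilibrium_policy,
    kl_divergence,
)

__all__ = [
    "MarkovKernel",
    "rejection_decide",
    "rejection_decide_many",
    "expected_sample_count",
    "anytime_rejection_policy",
    "sample_anytime_rejection",
    "mh_discrete_kernel",
    "equilibrium_kernel",
    "mh_continuous_chain",
    "detailed_balance_residual",
]

#: hard cap on rejection-sampling draws before a diagnostic is raised
MAX_REJECTION_DRAWS = 10**7


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


@dataclass(frozen=True)
class MarkovKernel:
    """Row-stochastic transition kernel over a finite action space, log domain.

    ``logtrans[i, j]`` is the log-probability of moving from action ``i`` to
    action ``j``; each row normalizes to 1 within 1e-12.
    """

    space: ActionSpace
    logtrans: np.ndarray

    def __post_init__(self):
        lt = np.asarray(self.logtrans, dtype=float)
        n = self.space.size
        if lt.shape != (n, n):
            raise ValueError("kernel shape does not match action space")
        norms = logsumexp(lt, axis=1)
        if np.max(np.abs(norms)) > 1e-9:
            raise ValueError("kernel rows do not normalize")
        object.__setattr__(self, "logtrans", lt - norms[:, None])

    @property
    def trans(self) -> np.ndarray:
        return np.exp(self.logtrans)

    def stationary(self) -> Policy:
        """Stationary distribution via the leading left eigenvector."""
        vals, vecs = np.linalg.eig(self.trans.T)
        i = int(np.argmax(vals.real))
        v = np.abs(vecs[:, i].real)
        with np.errstate(divide="ignore"):
            return Policy(self.space, np.log(v / v.sum()))


def _check_aspiration(delta_u: UtilityEpoch, T: float) -> float:
    T = float(T)
    if T < np.max(delta_u.values) - 1e-12:
        raise ValueError(
            "aspiration level T must dominate the maximum utility change"
        )
    return T


def rejection_decide(
    prior: Policy, delta_u: UtilityEpoch, beta: float, T: float, rng
) -> tuple[int, int]:
    """One rejection-sampling decision.

    Returns ``(action index, number of prior draws used)``.  The accepted
    action is distributed exactly as the equilibrium policy for any valid
    aspiration level.
    """
    T = _check_aspiration(delta_u, T)
    rng = _as_rng(rng)
    log_acc = beta * (delta_u.values - T)  # <= 0
    probs = prior.probs
    n = 0
    while True:
        x = int(rng.choice(prior.space.size, p=probs))
        n += 1
        if np.log(rng.random()) <= log_acc[x]:
            return x, n
        if n >= MAX_REJECTION_DRAWS:
            raise RuntimeError(
                "rejection sampler exceeded the draw cap; "
                "beta * (T - max dU) is likely far too large"
            )


def rejection_decide_many(
    prior: Policy, delta_u: UtilityEpoch, beta: float, T: float, n_decisions: int, rng
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized batch of independent rejection-sampling decisions.

    Returns ``(actions, draw counts)``, each of length ``n_decisions``.
    """
    T = _check_aspiration(delta_u, T)
    rng = _as_rng(rng)
    acc = np.exp(beta * (delta_u.values - T))
    probs = prior.probs
    actions = np.empty(n_decisions, dtype=np.int64)
    draws = np.zeros(n_decisions, dtype=np.int64)
    pending = np.arange(n_decisions)
    rounds = 0
    while pending.size:
        x = rng.choice(prior.space.size, size=pending.size, p=probs)
        accept = rng.random(pending.size) <= acc[x]
        draws[pending] += 1
        actions[pending[accept]] = x[accept]
        pending = pending[~accept]
        rounds += 1
        if rounds >= MAX_REJECTION_DRAWS:
            raise RuntimeError("rejection sampler exceeded the draw cap")
    return actions, draws


def expected_sample_count(
    prior: Policy, delta_u: UtilityEpoch, beta: float, T: float
) -> float:
    """Expected prior draws per accepted decision, ``exp(beta T) / Z_beta``.

    Lower-bounded by ``exp(KL(p_eq || p0))``: the further the equilibrium
    policy moves from the prior, the more samples a decision costs.
    """
    T = _check_aspiration(delta_u, T)
    log_z = logsumexp(prior.logp + beta * delta_u.values)
    return float(np.exp(beta * T - log_z))


def anytime_rejection_policy(
    prior: Policy, delta_u: UtilityEpoch, beta: float, T: float, k: int
) -> Policy:
    """Non-equilibrium policy of rejection sampling interrupted after ``k`` draws.

    The exact mixture ``(1 - q_k) p_eq + q_k p0`` with
    ``q_k = (1 - Z_beta exp(-beta T))^k``; ``k = 0`` returns the prior
    (no computation performed), ``k -> inf`` the equilibrium policy.
    """
    T = _check_aspiration(delta_u, T)
    k = int(k)
    if k < 0:
        raise ValueError("budget k must be non-negative")
    if k == 0:
        return prior
    log_z = logsumexp(prior.logp + beta * delta_u.values)
    p_accept = np.exp(log_z - beta * T)  # per-draw acceptance probability
    q_k = (1.0 - p_accept) ** k
    eq = equilibrium_policy(prior, delta_u, beta)
    mix = (1.0 - q_k) * eq.probs + q_k * prior.probs
    with np.errstate(divide="ignore"):
        return Policy(prior.space, np.log(mix) - np.log(mix.sum()))


def sample_anytime_rejection(
    prior: Policy, delta_u: UtilityEpoch, beta: float, T: float, k: int,
    n_decisions: int, rng,
) -> np.ndarray:
    """Simulate the anytime rejection decision-maker.

    Each decision makes at most ``k`` accept/reject attempts; if none is
    accepted, a fresh prior draw is emitted (the emission rule under which
    the closed-form mixture is exact).
    """
    T = _check_aspiration(delta_u, T)
    rng = _as_rng(rng)
    acc = np.exp(beta * (delta_u.values - T))
    probs = prior.probs
    actions = np.empty(n_decisions, dtype=np.int64)
    pending = np.arange(n_decisions)
    for _ in range(int(k)):
        if not pending.size:
            break
        x = rng.choice(prior.space.size, size=pending.size, p=probs)
        accept = rng.random(pending.size) <= acc[x]
        actions[pending[accept]] = x[accept]
        pending = pending[~accept]
    if pending.size:
        actions[pending] = rng.choice(prior.space.size, size=pending.size, p=probs)
    return actions


def mh_discrete_kernel(prior: Policy, utility: UtilityEpoch, beta: float) -> MarkovKernel:
    """One-step Metropolis-Hastings kernel with the prior as proposal.

    Off-diagonal entries are ``p0(x') min(1, exp(beta (U(x') - U(x))))``;
    the rejection mass is folded into the diagonal so the kernel is a proper
    stochastic matrix.  Detailed balance holds with respect to the
    equilibrium policy ``p0 exp(beta U) / Z``.
    """
    if utility.size != prior.space.size:
        raise ValueError("utility vector does not match the action space")
    n = prior.space.size
    u = utility.values
    log_acc = np.minimum(0.0, beta * (u[None, :] - u[:, None]))  # [from, to]
    log_off = prior.logp[None, :] + log_acc
    off = np.exp(log_off)
    np.fill_diagonal(off, 0.0)
    diag = 1.0 - off.sum(axis=1)
    diag = np.clip(diag, 0.0, None)
    trans = off + np.diag(diag)
    trans /= trans.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore"):
        return MarkovKernel(prior.space, np.log(trans))


def equilibrium_kernel(prior: Policy, utility: UtilityEpoch, beta: float) -> MarkovKernel:
    """Fully equilibrating (independence) kernel: every row is the equilibrium policy.

    The limit of running the Metropolis-Hastings chain to convergence within
    an epoch; trivially detailed-balanced with respect to its stationary law.
    """
    eq = equilibrium_policy(prior, utility, beta)
    return MarkovKernel(prior.space, np.tile(eq.logp, (prior.space.size, 1)))


def detailed_balance_residual(kernel: MarkovKernel, stationary: Policy) -> float:
    """Max over ordered pairs of ``|p(x) K(x'|x) - p(x') K(x|x')|``."""
    if kernel.space is not stationary.space and kernel.space != stationary.space:
        raise ValueError("kernel and stationary policy share no action space")
    flow = stationary.probs[:, None] * kernel.trans
    return float(np.max(np.abs(flow - flow.T)))


def mh_continuous_chain(
    x0: float,
    utility: QuadraticUtility,
    beta: float,
    sigma_p: float,
    n_steps: int,
    rng,
) -> tuple[np.ndarray, np.ndarray]:
    """Metropolis-Hastings chain on the real line with a Gaussian random walk.

    The symmetric proposal ``N(x' ; x, sigma_p^2)`` cancels in the acceptance
    ratio ``min(1, exp(beta (U(x') - U(x))))``.  Returns the chain states
    (``n_steps + 1`` values including the start) and a boolean mask marking
    which steps were accepted moves.
    """
    if not sigma_p > 0:
        raise ValueError("proposal standard deviation must be positive")
    rng = _as_rng(rng)
    xs = np.empty(n_steps + 1)
    accepted = np.zeros(n_steps + 1, dtype=bool)
    xs[0] = x = float(x0)
    u_cur = float(utility.u(x))
    # pre-drawn noise keeps the loop tight
    steps = rng.normal(0.0, sigma_p, size=n_steps)
    logu = np.log(rng.random(n_steps))
    for i in range(n_steps):
        xp = x + steps[i]
        u_prop = float(utility.u(xp))
        if logu[i] <= beta * (u_prop - u_cur):
            x, u_cur = xp, u_prop
            accepted[i + 1] = True
        xs[i + 1] = x
    return xs, accepted


def sample_count_lower_bound(prior: Policy, delta_u: UtilityEpoch, beta: float) -> float:
    """``exp(KL(p_eq || p0))``, the information-theoretic floor on sample cost."""
    eq = equilibrium_policy(prior, delta_u, beta)
    return float(np.exp(kl_divergence(eq, prior)))
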