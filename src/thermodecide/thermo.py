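"""Trajectory-level thermodynamic accounting for adapting decision-makers.

A changing environment is a *protocol*: a time-indexed sequence of utility
functions ``U(x, t_0), ..., U(x, t_N)`` over one action space, driven
externally (the decision-maker's actions never influence it).  A trajectory
``x = (x_0, ..., x_N)`` records the action held at each epoch.  This module
keeps the books for such trajectories:

* the *utility gain* (work analog) collected as the environment shifts,
* the *deliberation cost* — the stochastic-entropy difference between the
  posterior and prior conditional choice probabilities, charged at ``1/beta``,
* the *net utility* ``U_net`` (gain minus cost) and the *dissipated utility*
  ``U_diss = dF - U_net``, where ``dF`` is the equilibrium free-energy
  difference of the protocol,
* forward and backward trajectory log-probabilities, whose per-trajectory
  log-ratio equals ``beta * U_diss`` exactly (Crooks-type fluctuation
  theorem), and whose exponential-average links finite-time behaviour to
  ``dF`` (Jarzynski-type equality).

Three regimes are supported.  In the *no-deliberation* regime the action is
held while the utility changes and the decision-maker relaxes only
afterwards (the one-step-lag learner); in the *deliberation* regime the
action is chosen after partial adaptation through a detailed-balanced Markov
kernel; in the *episodic-fixed-prior* regime every episode restarts from the
same prior and the choice distribution is an interrupted (anytime) sampler.

Equilibria are taken relative to a prior strategy ``p0``:
``p_eq(x | t) = p0(x) exp(beta U(x, t)) / Z_t`` with
``Z_t = sum_x p0(x) exp(beta U(x, t))`` and
``dF = (1/beta) log(Z_N / Z_0)``.  The fluctuation identities hold in this
generalized form because the prior log-weights telescope out of the
forward/backward ratio.

Reversal conventions.  The backward measure starts from the equilibrium at
the final epoch and reverses each forward transition through detailed
balance.  Which epoch's kernel performs the reversal depends on the step
ordering of the regime: in the deliberation regime the move at step ``n``
pairs with the utility change ``t_{n-1} -> t_n`` evaluated *after* the move,
and the reversal uses the kernel at ``t_{n-1}``; in the no-deliberation
regime the utility change is evaluated *before* the relaxation (which
happens under the new utility ``t_n``), and the reversal uses the kernel at
``t_n``.  Each convention makes the corresponding Crooks identity exact, as
the enumeration oracles in the test-suite verify trajectory by trajectory.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from .policy import ActionSpace, Policy, UtilityEpoch, equilibrium_policy
from .samplers import MarkovKernel, detailed_balance_residual, equilibrium_kernel, mh_discrete_kernel

__all__ = [
    "REGIMES",
    "UtilityProtocol",
    "DecisionTrajectory",
    "ThermoLedger",
    "JarzynskiEstimate",
    "delta_free_energy",
    "utility_gain_no_deliberation",
    "deliberation_cost",
    "net_utility_deliberation",
    "episodic_net_utility",
    "episodic_delta_free_energy",
    "dissipated_utility",
    "forward_trajectory_logprob",
    "backward_trajectory_logprob",
    "crooks_check",
    "jarzynski_estimate",
    "second_law_check",
    "accepted_path_logprob",
    "mh_protocol_kernels",
    "lag_protocol_kernels",
    "kernel_power",
    "enumerate_trajectories",
    "sample_trajectories",
    "trajectory_ledger",
]

REGIMES = ("no-deliberation", "deliberation", "episodic-fixed-prior")

#: trajectory enumeration cap; larger instances must be sampled instead
MAX_ENUMERATION = 10**6


@dataclass(frozen=True)
class UtilityProtocol:
    """Ordered sequence of tabular utility epochs over one action space."""

    space: ActionSpace
    epochs: tuple

    def __init__(self, space: ActionSpace, epochs: Sequence[UtilityEpoch]):
        epochs = tuple(
            e if isinstance(e, UtilityEpoch) else UtilityEpoch(np.asarray(e, float), i)
            for i, e in enumerate(epochs)
        )
        if len(epochs) < 2:
            raise ValueError("a protocol needs at least two epochs")
        for e in epochs:
            if e.size != space.size:
                raise ValueError("epoch utility does not match the action space")
        object.__setattr__(self, "space", space)
        object.__setattr__(self, "epochs", epochs)

    @property
    def n_transitions(self) -> int:
        return len(self.epochs) - 1

    def u(self, n: int) -> np.ndarray:
        return self.epochs[n].values

    def reversed(self) -> "UtilityProtocol":
        return UtilityProtocol(self.space, tuple(reversed(self.epochs)))


@dataclass(frozen=True)
class DecisionTrajectory:
    """Ordered actions ``x_0 ... x_N`` with the regime they were produced under."""

    actions: np.ndarray
    regime: str

    def __post_init__(self):
        if self.regime not in REGIMES:
            raise ValueError(f"unknown regime {self.regime!r}; expected one of {REGIMES}")
        object.__setattr__(self, "actions", np.asarray(self.actions))

    def __len__(self) -> int:
        return len(self.actions)


@dataclass(frozen=True)
class ThermoLedger:
    """Per-trajectory account: gains, costs, net/dissipated utility, path log-probs."""

    gains: np.ndarray
    costs: np.ndarray  # deliberation log-ratios in nats (before the 1/beta factor)
    u_net: float
    u_diss: float
    fwd_logp: float
    bwd_logp: float
    warnings: tuple = ()


@dataclass(frozen=True)
class JarzynskiEstimate:
    """Running empirical mean of ``exp(beta U_net)`` with its standard error."""

    n: int
    mean: float
    se: float
    beta: float

    @property
    def free_energy_estimate(self) -> float:
        return math.log(self.mean) / self.beta


def _check_regime(traj: DecisionTrajectory, expected: str):
    if traj.regime != expected:
        raise ValueError(f"trajectory regime is {traj.regime!r}, expected {expected!r}")


def _log_partition(prior: Policy, u: np.ndarray, beta: float) -> float:
    return float(logsumexp(prior.logp + beta * u))


def _eq_logp(prior: Policy, u: np.ndarray, beta: float) -> np.ndarray:
    logw = prior.logp + beta * u
    return logw - logsumexp(logw)


def delta_free_energy(prior: Policy, protocol: UtilityProtocol, beta: float) -> float:
    """Equilibrium free-energy difference ``(1/beta) log(Z_N / Z_0)`` of a protocol."""
    if beta <= 0:
        raise ValueError("delta_free_energy requires beta > 0")
    z0 = _log_partition(prior, protocol.u(0), beta)
    zn = _log_partition(prior, protocol.u(protocol.n_transitions), beta)
    return (zn - z0) / beta


# ---------------------------------------------------------------------------
# kernels along a protocol


def kernel_power(kernel: MarkovKernel, k: int) -> MarkovKernel:
    """k-fold composition of a kernel (k sweeps of the underlying sampler)."""
    if k < 1:
        raise ValueError("kernel power requires k >= 1")
    with np.errstate(divide="ignore"):
        return MarkovKernel(
            kernel.space, np.log(np.linalg.matrix_power(kernel.trans, int(k)))
        )


def mh_protocol_kernels(
    prior: Policy, protocol: UtilityProtocol, beta: float, sweeps: int = 1
) -> list[MarkovKernel]:
    """Per-epoch kernels for the deliberation regime.

    Epoch 0 gets the fully-equilibrating kernel (the decision-maker starts
    in equilibrium, so its epoch-0 conditional is the equilibrium policy
    regardless of the previous action); epochs 1..N get ``sweeps`` steps of
    the prior-proposal Metropolis-Hastings kernel at that epoch's utility.
    """
    kernels = [equilibrium_kernel(prior, protocol.epochs[0], beta)]
    for epoch in protocol.epochs[1:]:
        k = mh_discrete_kernel(prior, epoch, beta)
        kernels.append(kernel_power(k, sweeps) if sweeps > 1 else k)
    return kernels


def lag_protocol_kernels(
    prior: Policy, protocol: UtilityProtocol, beta: float
) -> list[MarkovKernel]:
    """Fully-equilibrating kernels at every epoch (the one-step-lag learner)."""
    return [equilibrium_kernel(prior, e, beta) for e in protocol.epochs]


# ---------------------------------------------------------------------------
# per-trajectory quantities


def utility_gain_no_deliberation(
    traj: DecisionTrajectory, protocol: UtilityProtocol
) -> float:
    """Total utility gain ``sum_n U(x_{n-1}, t_n) - U(x_{n-1}, t_{n-1})``.

    The work analog of the lagging decision-maker: the environment shifts
    while the action is held, so the gain is evaluated at the *previous*
    action and the final decision ``x_N`` never contributes.
    """
    _check_regime(traj, "no-deliberation")
    x = traj.actions
    total = 0.0
    for n in range(1, protocol.n_transitions + 1):
        total += protocol.u(n)[x[n - 1]] - protocol.u(n - 1)[x[n - 1]]
    return float(total)


def deliberation_cost(
    x_n: int, x_prev: int, kernel_now: MarkovKernel, kernel_prev: MarkovKernel
) -> float:
    """Stochastic-entropy difference ``log p(x_n|x_prev, t_n) - log p(x_n|x_prev, t_{n-1})``.

    Returned in nats; the caller applies the ``1/beta`` conversion to
    utility units.  Undefined (raises) when the prior conditional assigns
    zero probability to the chosen action.
    """
    log_now = kernel_now.logtrans[x_prev, x_n]
    log_prev = kernel_prev.logtrans[x_prev, x_n]
    if log_prev == -np.inf:
        raise ValueError("deliberation cost undefined: zero prior conditional probability")
    return float(log_now - log_prev)


def net_utility_deliberation(
    traj: DecisionTrajectory,
    protocol: UtilityProtocol,
    kernels: Sequence[MarkovKernel],
    beta: float,
) -> float:
    """Net utility ``sum_n [U(x_n,t_n) - U(x_n,t_{n-1}) - (1/beta) cost_n]``.

    ``kernels[n]`` is the conditional in force at epoch ``n``; ``kernels[0]``
    must be the equilibrium policy at ``t_0`` (independent of conditioning).
    """
    _check_regime(traj, "deliberation")
    x = traj.actions
    total = 0.0
    for n in range(1, protocol.n_transitions + 1):
        gain = protocol.u(n)[x[n]] - protocol.u(n - 1)[x[n]]
        cost = deliberation_cost(int(x[n]), int(x[n - 1]), kernels[n], kernels[n - 1])
        total += gain - cost / beta
    return float(total)


def episodic_net_utility(
    traj: DecisionTrajectory,
    delta_us: Sequence[UtilityEpoch],
    policies: Sequence[Policy],
    prior: Policy,
    beta: float,
) -> float:
    """Net utility of independent episodes under a fixed prior.

    ``sum_n [dU_n(x_n) - (1/beta) log(p_n(x_n) / p0(x_n))]`` where ``p_n``
    is the (possibly non-equilibrium) per-episode choice policy.
    """
    _check_regime(traj, "episodic-fixed-prior")
    x = traj.actions
    if len(x) != len(delta_us) or len(policies) != len(delta_us):
        raise ValueError("trajectory, utilities and policies must have equal length")
    total = 0.0
    for n, (du, pol) in enumerate(zip(delta_us, policies)):
        if pol.logp[x[n]] == -np.inf:
            raise ValueError("episode policy assigns zero probability to the chosen action")
        total += du.values[x[n]] - (pol.logp[x[n]] - prior.logp[x[n]]) / beta
    return float(total)


def episodic_delta_free_energy(
    prior: Policy, delta_us: Sequence[UtilityEpoch], beta: float
) -> float:
    """Sum of per-episode equilibrium free energies ``(1/beta) log Z_n``."""
    return float(sum(_log_partition(prior, du.values, beta) for du in delta_us)) / beta


def dissipated_utility(u_net: float, delta_f: float) -> float:
    """Dissipation ``U_diss = dF - U_net``: utility lost to imperfect adaptation."""
    return float(delta_f - u_net)


# ---------------------------------------------------------------------------
# trajectory measures


def forward_trajectory_logprob(
    traj: DecisionTrajectory,
    kernels: Sequence[MarkovKernel],
    initial_policy: Policy,
) -> float:
    """Log-probability of a trajectory: equilibrium start, then the epoch kernels."""
    x = traj.actions
    logp = float(initial_policy.logp[x[0]])
    for n in range(1, len(x)):
        logp += float(kernels[n].logtrans[x[n - 1], x[n]])
    return logp


def backward_trajectory_logprob(
    traj: DecisionTrajectory,
    protocol: UtilityProtocol,
    kernels: Sequence[MarkovKernel],
    prior: Policy,
    beta: float,
) -> float:
    """Log-probability of the reversed trajectory under the reversed protocol.

    Starts from the equilibrium at the final epoch and reverses each forward
    transition through detailed balance:

    ``p_rev(x_{n-1} | x_n, t) = p_eq(x_{n-1}|t) K_t(x_n | x_{n-1}) / p_eq(x_n|t)``

    with the reversal epoch ``t = t_{n-1}`` in the deliberation regime and
    ``t = t_n`` in the no-deliberation regime (see the module docstring).
    """
    x = traj.actions
    N = protocol.n_transitions
    logp = float(_eq_logp(prior, protocol.u(N), beta)[x[N]])
    for n in range(1, N + 1):
        if traj.regime == "deliberation":
            t = n - 1
        elif traj.regime == "no-deliberation":
            t = n
        else:
            raise ValueError("backward measure defined for the two sequential regimes only")
        eq = _eq_logp(prior, protocol.u(t), beta)
        logp += float(eq[x[n - 1]] - eq[x[n]] + kernels[t].logtrans[x[n - 1], x[n]])
    return logp


def crooks_check(
    traj: DecisionTrajectory,
    protocol: UtilityProtocol,
    kernels: Sequence[MarkovKernel],
    prior: Policy,
    beta: float,
) -> tuple[float, float]:
    """Both sides of the fluctuation theorem, in log form.

    Returns ``(log p(x) - log p_rev(x), beta * U_diss(x))``; the theorem
    asserts their equality for every trajectory.
    """
    eq0 = Policy(prior.space, _eq_logp(prior, protocol.u(0), beta))
    fwd = forward_trajectory_logprob(traj, kernels, eq0)
    bwd = backward_trajectory_logprob(traj, protocol, kernels, prior, beta)
    dF = delta_free_energy(prior, protocol, beta)
    if traj.regime == "deliberation":
        u_net = net_utility_deliberation(traj, protocol, kernels, beta)
    elif traj.regime == "no-deliberation":
        u_net = utility_gain_no_deliberation(traj, protocol)
    else:
        raise ValueError("crooks_check covers the two sequential regimes")
    return fwd - bwd, beta * dissipated_utility(u_net, dF)


def trajectory_ledger(
    traj: DecisionTrajectory,
    protocol: UtilityProtocol,
    kernels: Sequence[MarkovKernel],
    prior: Policy,
    beta: float,
) -> ThermoLedger:
    """Full per-trajectory account (gains, costs, U_net, U_diss, path log-probs).

    Records a warning when a supplied kernel fails detailed balance with
    respect to its epoch equilibrium (residual above 1e-9), in which case
    the fluctuation identities are not guaranteed.
    """
    x = traj.actions
    N = protocol.n_transitions
    warnings = []
    for n in range(1, N + 1):
        eq = Policy(prior.space, _eq_logp(prior, protocol.u(n), beta))
        res = detailed_balance_residual(kernels[n], eq)
        if res > 1e-9:
            warnings.append(f"kernel at epoch {n} violates detailed balance (residual {res:.2e})")
    gains = np.empty(N)
    costs = np.zeros(N)
    if traj.regime == "deliberation":
        for n in range(1, N + 1):
            gains[n - 1] = protocol.u(n)[x[n]] - protocol.u(n - 1)[x[n]]
            costs[n - 1] = deliberation_cost(int(x[n]), int(x[n - 1]), kernels[n], kernels[n - 1])
        u_net = float(gains.sum() - costs.sum() / beta)
    elif traj.regime == "no-deliberation":
        for n in range(1, N + 1):
            gains[n - 1] = protocol.u(n)[x[n - 1]] - protocol.u(n - 1)[x[n - 1]]
        u_net = float(gains.sum())
    else:
        raise ValueError("trajectory_ledger covers the two sequential regimes")
    dF = delta_free_energy(prior, protocol, beta)
    eq0 = Policy(prior.space, _eq_logp(prior, protocol.u(0), beta))
    fwd = forward_trajectory_logprob(traj, kernels, eq0)
    bwd = backward_trajectory_logprob(traj, protocol, kernels, prior, beta)
    return ThermoLedger(
        gains=gains,
        costs=costs,
        u_net=u_net,
        u_diss=dissipated_utility(u_net, dF),
        fwd_logp=fwd,
        bwd_logp=bwd,
        warnings=tuple(warnings),
    )


# ---------------------------------------------------------------------------
# ensembles: enumeration and sampling


def enumerate_trajectories(
    protocol: UtilityProtocol,
    kernels: Sequence[MarkovKernel],
    prior: Policy,
    beta: float,
    regime: str = "deliberation",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Exhaustively enumerate all trajectories of a small discrete instance.

    Returns ``(trajectories [M, N+1], forward log-probs [M], u_net [M])``.
    The forward measure sums to one over the enumeration; instances beyond
    ``MAX_ENUMERATION`` paths raise (sample instead).
    """
    S = protocol.space.size
    N = protocol.n_transitions
    if S ** (N + 1) > MAX_ENUMERATION:
        raise ValueError(
            f"{S ** (N + 1)} trajectories exceed the enumeration cap; "
            "use sample_trajectories instead"
        )
    trajs = np.array(list(itertools.product(range(S), repeat=N + 1)), dtype=np.int64)
    eq0 = _eq_logp(prior, protocol.u(0), beta)
    fwd = eq0[trajs[:, 0]].copy()
    for n in range(1, N + 1):
        fwd += kernels[n].logtrans[trajs[:, n - 1], trajs[:, n]]
    u_net = np.empty(len(trajs))
    if regime == "deliberation":
        u_net[:] = 0.0
        for n in range(1, N + 1):
            gain = protocol.u(n)[trajs[:, n]] - protocol.u(n - 1)[trajs[:, n]]
            cost = (
                kernels[n].logtrans[trajs[:, n - 1], trajs[:, n]]
                - kernels[n - 1].logtrans[trajs[:, n - 1], trajs[:, n]]
            )
            u_net += gain - cost / beta
    elif regime == "no-deliberation":
        u_net[:] = 0.0
        for n in range(1, N + 1):
            u_net += protocol.u(n)[trajs[:, n - 1]] - protocol.u(n - 1)[trajs[:, n - 1]]
    else:
        raise ValueError("enumeration covers the two sequential regimes")
    return trajs, fwd, u_net


def sample_trajectories(
    protocol: UtilityProtocol,
    kernels: Sequence[MarkovKernel],
    prior: Policy,
    beta: float,
    n_trajectories: int,
    rng,
    regime: str = "deliberation",
) -> tuple[np.ndarray, np.ndarray]:
    """Draw i.i.d. forward trajectories; returns ``(trajectories, u_net)``."""
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    S = protocol.space.size
    N = protocol.n_transitions
    trajs = np.empty((n_trajectories, N + 1), dtype=np.int64)
    eq0 = np.exp(_eq_logp(prior, protocol.u(0), beta))
    trajs[:, 0] = rng.choice(S, size=n_trajectories, p=eq0)
    for n in range(1, N + 1):
        cdf = np.cumsum(kernels[n].trans, axis=1)
        u = rng.random(n_trajectories)
        rows = cdf[trajs[:, n - 1]]
        trajs[:, n] = np.minimum((rows < u[:, None]).sum(axis=1), S - 1)
    u_net = np.zeros(n_trajectories)
    if regime == "deliberation":
        for n in range(1, N + 1):
            gain = protocol.u(n)[trajs[:, n]] - protocol.u(n - 1)[trajs[:, n]]
            cost = (
                kernels[n].logtrans[trajs[:, n - 1], trajs[:, n]]
                - kernels[n - 1].logtrans[trajs[:, n - 1], trajs[:, n]]
            )
            u_net += gain - cost / beta
    elif regime == "no-deliberation":
        for n in range(1, N + 1):
            u_net += protocol.u(n)[trajs[:, n - 1]] - protocol.u(n - 1)[trajs[:, n - 1]]
    else:
        raise ValueError("sampling covers the two sequential regimes")
    return trajs, u_net


# ---------------------------------------------------------------------------
# estimators


def jarzynski_estimate(u_net: np.ndarray, beta: float) -> JarzynskiEstimate:
    """Empirical mean of ``exp(beta U_net)`` with standard error, log-domain safe.

    The implied free-energy estimate ``(1/beta) log(mean)`` never falls below
    the sample-mean net utility (Jensen), which the estimator preserves
    deterministically.
    """
    u_net = np.asarray(u_net, dtype=float)
    n = u_net.size
    if n == 0:
        raise ValueError("jarzynski_estimate requires at least one trajectory")
    if beta <= 0:
        raise ValueError("jarzynski_estimate requires beta > 0")
    logw = beta * u_net
    shift = float(np.max(logw))
    s = np.exp(logw - shift)
    mean = float(np.exp(shift) * s.mean())
    se = float(np.exp(shift) * s.std(ddof=1) / math.sqrt(n)) if n > 1 else float("nan")
    return JarzynskiEstimate(n=n, mean=mean, se=se, beta=beta)


def second_law_check(
    u_diss: np.ndarray,
    fwd_logp: np.ndarray,
    bwd_logp: np.ndarray,
    beta: float,
    weights: np.ndarray | None = None,
) -> tuple[float, float]:
    """Mean dissipation and the matching relative-entropy estimate.

    With ``weights=None`` the inputs are i.i.d. forward samples and both
    returns are plain means; with explicit forward-measure weights (an
    enumeration) both are exact expectations.  The second law asserts that
    either quantity is non-negative and that the two coincide:
    ``<U_diss> = (1/beta) KL(p || p_rev)``.
    """
    u_diss = np.asarray(u_diss, float)
    log_ratio = np.asarray(fwd_logp, float) - np.asarray(bwd_logp, float)
    if weights is None:
        return float(u_diss.mean()), float(log_ratio.mean() / beta)
    weights = np.asarray(weights, float)
    weights = weights / weights.sum()
    return float(weights @ u_diss), float(weights @ log_ratio / beta)


# ---------------------------------------------------------------------------
# accepted-move path probabilities (continuous Metropolis-Hastings chains)


def accepted_path_logprob(
    path: np.ndarray,
    utilities: Sequence,
    beta: float,
    sigma_p: float,
    initial_logpdf,
) -> float:
    """Log-density of a path of *accepted* Metropolis-Hastings moves.

    ``p(x) = p(x_0) prod_t g(x_t | x_{t-1}) alpha(x_t | x_{t-1})`` with a
    Gaussian random-walk proposal ``g`` of standard deviation ``sigma_p``
    and acceptance ``alpha = min(1, exp(beta (U_t(x_t) - U_t(x_{t-1}))))``
    under the utility in force at move ``t``.  Rejection events are not
    represented, so this is not the full chain measure — it is the
    accepted-move convention used for scoring adaptation (hysteresis)
    trajectories; the kernel-based measures above are the ones entering the
    fluctuation-theorem oracles.

    ``utilities[t-1]`` must provide ``u(x)`` for move ``t``;
    ``initial_logpdf`` maps ``x_0`` to its starting log-density.
    """
    path = np.asarray(path, dtype=float)
    if len(path) != len(utilities) + 1:
        raise ValueError("need one utility per move (len(path) - 1)")
    if not sigma_p > 0:
        raise ValueError("proposal standard deviation must be positive")
    logp = float(initial_logpdf(path[0]))
    log_norm = -0.5 * math.log(2.0 * math.pi * sigma_p**2)
    for t in range(1, len(path)):
        step = path[t] - path[t - 1]
        logp += log_norm - 0.5 * step**2 / sigma_p**2
        du = float(utilities[t - 1].u(path[t]) - utilities[t - 1].u(path[t - 1]))
        logp += min(0.0, beta * du)
    return logp
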