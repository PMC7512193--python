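"""Equilibrium (bounded-optimal) policies and the free-energy functional.

A bounded-rational decision-maker trades expected utility gain against the
information cost of moving away from a prior strategy, measured by the
Kullback-Leibler divergence.  For a finite action set the optimal trade-off

    ``F[p] = E_p[dU] - (1/beta) KL(p || p0)``

is maximised by a Boltzmann-like tilt of the prior,

    ``p_eq(x) = p0(x) exp(beta dU(x)) / Z_beta``,

whose attained value ``(1/beta) log Z_beta`` is the certainty-equivalent
value of the decision problem.  The inverse temperature ``beta`` converts
informational units into utility units: ``beta -> 0`` models a decision-maker
that cannot afford any processing (the prior is returned), ``beta -> inf`` a
perfectly rational one (all mass on the argmax set).

All probability arithmetic is carried out in the log domain with
log-sum-exp so that large ``beta * dU`` products never overflow.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "ActionSpace",
    "Policy",
    "UtilityEpoch",
    "QuadraticUtility",
    "kl_divergence",
    "equilibrium_policy",
    "equilibrium_free_energy",
    "free_energy_functional",
]

_NORM_TOL = 1e-12


@dataclass(frozen=True)
class ActionSpace:
    """A finite set of distinct action identifiers."""

    labels: tuple

    def __init__(self, labels: Sequence):
        labels = tuple(labels)
        if len(labels) < 1:
            raise ValueError("action space must contain at least one action")
        if len(set(labels)) != len(labels):
            raise ValueError("action labels must be unique")
        object.__setattr__(self, "labels", labels)

    @property
    def size(self) -> int:
        return len(self.labels)

    def index(self, label) -> int:
        return self.labels.index(label)


@dataclass(frozen=True)
class Policy:
    """A normalized distribution over a finite action set, stored in log domain.

    Entries may be ``-inf`` (zero probability) but the vector must normalize:
    ``logsumexp(logp) == 0`` within 1e-12.
    """

    space: ActionSpace
    logp: np.ndarray

    def __post_init__(self):
        logp = np.asarray(self.logp, dtype=float)
        if logp.shape != (self.space.size,):
            raise ValueError("log-probability vector does not match action space")
        if np.any(np.isnan(logp)) or np.any(logp == np.inf):
            raise ValueError("log-probabilities must be finite or -inf")
        norm = logsumexp(logp)
        if abs(norm) > 1e-8:
            raise ValueError(f"policy not normalized: logsumexp = {norm}")
        if abs(norm) > _NORM_TOL:
            logp = logp - norm
        object.__setattr__(self, "logp", logp)

    @classmethod
    def from_probs(cls, space: ActionSpace, probs: Sequence[float]) -> "Policy":
        p = np.asarray(probs, dtype=float)
        if np.any(p < 0):
            raise ValueError("probabilities must be non-negative")
        with np.errstate(divide="ignore"):
            return cls(space, np.log(p / p.sum()))

    @classmethod
    def uniform(cls, space: ActionSpace) -> "Policy":
        return cls(space, np.full(space.size, -np.log(space.size)))

    @property
    def probs(self) -> np.ndarray:
        return np.exp(self.logp)

    def support(self) -> np.ndarray:
        return self.logp > -np.inf


@dataclass(frozen=True)
class UtilityEpoch:
    """A tabular utility function over a finite action space at one epoch."""

    values: np.ndarray
    epoch_index: int = 0

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(values)):
            raise ValueError("tabular utilities must be finite")
        object.__setattr__(self, "values", values)

    @property
    def size(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class QuadraticUtility:
    """Concave quadratic utility ``U(x) = -(a x^2 + b x) + offset`` on the reals.

    Concavity (``a > 0``) guarantees that ``exp(beta U)`` normalizes, so the
    bounded-optimal equilibrium is the Gaussian with mean ``-b / (2a)`` and
    variance ``1 / (2 beta a)``.  The offset cancels in every
    difference-of-utility quantity; it is carried only so that absolute
    utility curves can be reproduced.
    """

    a: float
    b: float
    offset: float = 0.0
    epoch_index: int = 0

    def __post_init__(self):
        if not self.a > 0:
            raise ValueError("quadratic utility requires a > 0 (concavity)")

    def u(self, x):
        x = np.asarray(x, dtype=float)
        return -(self.a * x**2 + self.b * x) + self.offset

    def du(self, x):
        """Derivative dU/dx."""
        x = np.asarray(x, dtype=float)
        return -(2.0 * self.a * x + self.b)

    @property
    def mode(self) -> float:
        return -self.b / (2.0 * self.a)

    def log_partition(self, beta: float) -> float:
        """log integral of exp(beta U) over the real line."""
        if beta <= 0:
            raise ValueError("log_partition requires beta > 0")
        return beta * (self.b**2 / (4.0 * self.a) + self.offset) + 0.5 * np.log(
            np.pi / (beta * self.a)
        )

    def equilibrium(self, beta: float) -> tuple[float, float]:
        """(mean, variance) of the Boltzmann-Gibbs Gaussian at inverse temperature beta."""
        if beta <= 0:
            raise ValueError("equilibrium requires beta > 0")
        return self.mode, 1.0 / (2.0 * beta * self.a)


def _check_beta(beta: float) -> float:
    beta = float(beta)
    if beta < 0:
        raise ValueError("inverse temperature beta must be non-negative")
    return beta


def _check_shared_space(*policies: Policy):
    spaces = {p.space for p in policies}
    if len(spaces) > 1:
        raise ValueError("policies do not share one action space")


def kl_divergence(p: Policy, q: Policy) -> float:
    """KL(p || q) in nats, with the 0 log 0 = 0 convention.

    Requires ``support(p) <= support(q)``; otherwise the divergence is
    undefined and an error is raised.
    """
    _check_shared_space(p, q)
    mask = p.logp > -np.inf
    if np.any(q.logp[mask] == -np.inf):
        raise ValueError("KL undefined: p has support where q has none")
    out = float(np.sum(np.exp(p.logp[mask]) * (p.logp[mask] - q.logp[mask])))
    return max(out, 0.0)


def equilibrium_policy(prior: Policy, delta_u: UtilityEpoch, beta: float) -> Policy:
    """Bounded-optimal policy ``p_eq(x) = p0(x) exp(beta dU(x)) / Z_beta``.

    ``beta = 0`` is handled as an explicit limit branch returning the prior.
    """
    beta = _check_beta(beta)
    if delta_u.size != prior.space.size:
        raise ValueError("utility vector does not match the action space")
    if not np.any(prior.logp > -np.inf):
        raise ValueError("prior has no support")
    if beta == 0.0:
        return prior
    logw = prior.logp + beta * delta_u.values
    return Policy(prior.space, logw - logsumexp(logw))


def equilibrium_free_energy(prior: Policy, delta_u: UtilityEpoch, beta: float) -> float:
    """Certainty-equivalent value ``(1/beta) log Z_beta`` of the decision problem.

    At ``beta = 0`` the limit value — the prior-expected utility change — is
    returned (the limit branch of the variational problem).
    """
    beta = _check_beta(beta)
    if delta_u.size != prior.space.size:
        raise ValueError("utility vector does not match the action space")
    if beta == 0.0:
        mask = prior.logp > -np.inf
        return float(np.sum(np.exp(prior.logp[mask]) * delta_u.values[mask]))
    return float(logsumexp(prior.logp + beta * delta_u.values)) / beta


def free_energy_functional(
    p: Policy, delta_u: UtilityEpoch, prior: Policy, beta: float
) -> float:
    """Free-energy trade-off ``E_p[dU] - (1/beta) KL(p || prior)``.

    Maximised (over p) by :func:`equilibrium_policy`, where it attains
    :func:`equilibrium_free_energy` exactly.
    """
    beta = _check_beta(beta)
    if beta == 0.0:
        raise ValueError("free_energy_functional requires beta > 0")
    _check_shared_space(p, prior)
    if delta_u.size != p.space.size:
        raise ValueError("utility vector does not match the action space")
    mask = p.logp > -np.inf
    expected = float(np.sum(np.exp(p.logp[mask]) * delta_u.values[mask]))
    return expected - kl_divergence(p, prior) / beta
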