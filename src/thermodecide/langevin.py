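"""Continuous deliberation as Langevin dynamics on a quadratic utility landscape.

The deliberating decision-maker performs noisy gradient ascent on the
current utility,

    ``dx/dt = alpha U'(x) + alpha xi(t)``,    ``<xi(t) xi(t')> = 2 D delta(t - t')``,

interrupted after time ``t = k dt`` to emit an action.  For concave
quadratic utilities ``U(x) = -(a x^2 + b x) + offset`` the associated
Fokker-Planck equation has a Gaussian solution at all times (an
Ornstein-Uhlenbeck process): starting from ``N(mu_0, sigma_0^2)``,

    ``mu(t)      = exp(-c t) mu_0 - (b / 2a) (1 - exp(-c t))``
    ``sigma^2(t) = sigma_inf^2 (1 - exp(-2 c t)) + sigma_0^2 exp(-2 c t)``

with relaxation rate ``c = 2 alpha a`` and stationary variance
``sigma_inf^2 = alpha D / (2 a)``.

Matching the stationary law to the Boltzmann-Gibbs form ``exp(beta U) / Z``
fixes the effective inverse temperature at ``beta_eff = 1 / (alpha D)``
(equivalently ``sigma_inf^2 = 1 / (2 beta_eff a)``); low noise means high
precision.  The derivation from the stationary Fokker-Planck equation is
unit-tested against simulation; :func:`printed_beta_relation` exposes the
alternative product form ``2 alpha D`` reported in parts of the literature,
which is inconsistent with the stationary solution and is surfaced in
experiment logs rather than silently used.

Because the finite-time transition density of the process is itself
Gaussian in closed form, trajectory net utilities, deliberation costs and
Jarzynski estimates are exact — no path discretization error enters the
fluctuation-relation checks.  The Euler-Maruyama integrator is provided to
validate the closed forms by simulation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .policy import QuadraticUtility

__all__ = [
    "LangevinConfig",
    "GaussianLaw",
    "gaussian_law",
    "effective_beta",
    "printed_beta_relation",
    "euler_maruyama_ensemble",
    "ou_transition",
    "langevin_net_utility",
    "langevin_delta_free_energy",
    "implicit_prior_utility",
]

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class LangevinConfig:
    """Parameters of the deliberation diffusion.

    alpha: learning rate multiplying both gradient and noise; D: noise
    scale; dt: integration step; n_steps: deliberation budget k (time
    ``k * dt``); (mu0, var0): initial Gaussian strategy.
    """

    alpha: float
    D: float
    dt: float
    n_steps: int
    mu0: float = 0.0
    var0: float = 1.0

    def __post_init__(self):
        if not (self.alpha > 0 and self.D > 0 and self.dt > 0):
            raise ValueError("alpha, D and dt must be positive")
        if not self.var0 > 0:
            raise ValueError("initial variance must be positive")
        if self.n_steps < 0:
            raise ValueError("step budget must be non-negative")

    @property
    def horizon(self) -> float:
        return self.n_steps * self.dt


@dataclass(frozen=True)
class GaussianLaw:
    """Marginal law of the deliberation process at one time."""

    mean: float
    var: float
    t: float

    def logpdf(self, x):
        x = np.asarray(x, dtype=float)
        return -0.5 * (_LOG_2PI + np.log(self.var)) - 0.5 * (x - self.mean) ** 2 / self.var


def effective_beta(config: LangevinConfig) -> float:
    """Inverse temperature of the stationary law: ``1 / (alpha D)``.

    Determined by matching the stationary Fokker-Planck solution
    ``p_inf ~ exp(U / (alpha D))`` to the Boltzmann-Gibbs form
    ``exp(beta U)``; invariant to the utility's linear coefficient and to
    the initial condition.
    """
    return 1.0 / (config.alpha * config.D)


def printed_beta_relation(config: LangevinConfig) -> float:
    """The product form ``2 alpha D`` sometimes quoted for the precision.

    Contradicts the stationary solution (and the monotonicity "less noise,
    more precision"); exposed for reporting only, never used in computation.
    """
    return 2.0 * config.alpha * config.D


def gaussian_law(config: LangevinConfig, utility: QuadraticUtility, t: float) -> GaussianLaw:
    """Closed-form marginal ``N(mu(t), sigma^2(t))`` of the diffusion at time ``t``."""
    if t < 0:
        raise ValueError("time must be non-negative")
    c = 2.0 * config.alpha * utility.a
    var_inf = config.alpha * config.D / (2.0 * utility.a)
    e1 = math.exp(-c * t)
    e2 = math.exp(-2.0 * c * t)
    mean = e1 * config.mu0 + utility.mode * (1.0 - e1)
    var = var_inf * (1.0 - e2) + config.var0 * e2
    return GaussianLaw(mean, var, t)


def euler_maruyama_ensemble(
    config: LangevinConfig,
    utility: QuadraticUtility,
    n_particles: int,
    rng,
    record_steps: Sequence[int] | None = None,
) -> dict[int, np.ndarray]:
    """Integrate the deliberation SDE for an ensemble of particles.

    ``x_{j+1} = x_j + alpha U'(x_j) dt + alpha sqrt(2 D dt) z``.  Returns
    particle positions at the requested step indices (default: only the
    final step).  A step size at or beyond the stability limit ``1/c`` of
    the linear drift triggers a warning.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    c = 2.0 * config.alpha * utility.a
    if config.dt >= 1.0 / c:
        warnings.warn(
            f"dt = {config.dt} at or beyond the stability limit 1/c = {1.0 / c:.3g}",
            RuntimeWarning,
            stacklevel=2,
        )
    record = sorted(set(record_steps)) if record_steps is not None else [config.n_steps]
    noise_scale = config.alpha * math.sqrt(2.0 * config.D * config.dt)
    x = rng.normal(config.mu0, math.sqrt(config.var0), size=n_particles)
    out: dict[int, np.ndarray] = {}
    if 0 in record:
        out[0] = x.copy()
    for j in range(1, config.n_steps + 1):
        x = x + config.alpha * utility.du(x) * config.dt + noise_scale * rng.normal(size=n_particles)
        if j in record:
            out[j] = x.copy()
    return out


def ou_transition(
    config: LangevinConfig, utility: QuadraticUtility, tau: float, x_prev: np.ndarray
) -> tuple[np.ndarray, float]:
    """Exact finite-time transition law of the diffusion from ``x_prev`` over ``tau``.

    Returns ``(conditional means, conditional variance)``; the kernel is
    detailed-balanced with respect to the stationary Gaussian.
    """
    c = 2.0 * config.alpha * utility.a
    var_inf = config.alpha * config.D / (2.0 * utility.a)
    e1 = math.exp(-c * tau)
    mean = utility.mode + e1 * (np.asarray(x_prev, dtype=float) - utility.mode)
    var = var_inf * (1.0 - math.exp(-2.0 * c * tau))
    return mean, float(var)


def implicit_prior_utility(config: LangevinConfig, beta: float) -> QuadraticUtility:
    """The quadratic utility whose equilibrium at ``beta`` is the initial Gaussian.

    Fluctuation relations require an equilibrium start; the initial strategy
    ``N(mu0, var0)`` is the Boltzmann-Gibbs law of
    ``a0 = 1 / (2 beta var0)``, ``b0 = -2 a0 mu0``.
    """
    a0 = 1.0 / (2.0 * beta * config.var0)
    return QuadraticUtility(a=a0, b=-2.0 * a0 * config.mu0, offset=0.0)


def langevin_delta_free_energy(
    config: LangevinConfig, utilities: Sequence[QuadraticUtility], beta: float
) -> float:
    """``(1/beta) log(Z_N / Z_0)`` from Gaussian integrals in closed form.

    Epoch 0 is the implicit prior utility of the initial strategy.
    """
    u0 = implicit_prior_utility(config, beta)
    return (utilities[-1].log_partition(beta) - u0.log_partition(beta)) / beta


def _normal_logpdf(x, mean, var):
    return -0.5 * (_LOG_2PI + np.log(var)) - 0.5 * (np.asarray(x) - mean) ** 2 / var


def langevin_net_utility(
    config: LangevinConfig,
    utilities: Sequence[QuadraticUtility],
    n_particles: int,
    rng=None,
    beta: float | None = None,
    normals: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Per-trajectory net utility for a sequence of deliberated decisions.

    The decision-maker starts in equilibrium ``N(mu0, var0)``, then for each
    epoch utility deliberates for time ``k dt`` (the exact transition
    kernel) and emits the reached state.  The net utility charges the
    utility change at the emitted action minus ``1/beta`` times the
    conditional log-probability shift from the previous epoch's kernel —
    with the epoch-0 conditional being the equilibrium start itself.
    Returns ``(U_net per particle, dF)``; the exponential average of
    ``beta U_net`` estimates ``exp(beta dF)`` (Jarzynski), and the sample
    mean obeys ``<U_net> <= dF``.

    ``beta`` defaults to the effective inverse temperature of the diffusion.
    ``normals`` (shape ``(n_particles, n_epochs + 1)``) optionally supplies
    the standard-normal draws, enabling common random numbers across a grid
    of deliberation budgets.
    """
    if normals is None:
        rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        normals = rng.standard_normal((n_particles, len(utilities) + 1))
    elif normals.shape != (n_particles, len(utilities) + 1):
        raise ValueError("normals must have shape (n_particles, n_epochs + 1)")
    if beta is None:
        beta = effective_beta(config)
    if beta <= 0:
        raise ValueError("beta must be positive")
    b_eff = effective_beta(config)
    if abs(beta - b_eff) > 1e-9 * max(1.0, abs(b_eff)):
        warnings.warn(
            "beta does not match the diffusion's effective inverse temperature; "
            "the kernels are then not detailed-balanced at this beta and the "
            "fluctuation relations need not hold",
            RuntimeWarning,
            stacklevel=2,
        )
    tau = config.horizon
    if tau <= 0:
        raise ValueError("deliberation horizon must be positive (n_steps >= 1)")
    epochs = [implicit_prior_utility(config, beta), *utilities]
    x_prev = config.mu0 + math.sqrt(config.var0) * normals[:, 0]
    u_net = np.zeros(n_particles)
    for n in range(1, len(epochs)):
        u_now = epochs[n]
        mean_now, var_now = ou_transition(config, u_now, tau, x_prev)
        x = mean_now + math.sqrt(var_now) * normals[:, n]
        gain = u_now.u(x) - epochs[n - 1].u(x)
        log_now = _normal_logpdf(x, mean_now, var_now)
        if n == 1:
            log_prev = _normal_logpdf(x, config.mu0, config.var0)
        else:
            mean_prev, var_prev = ou_transition(config, epochs[n - 1], tau, x_prev)
            log_prev = _normal_logpdf(x, mean_prev, var_prev)
        u_net += gain - (log_now - log_prev) / beta
        x_prev = x
    dF = langevin_delta_free_energy(config, utilities, beta)
    return u_net, dF
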