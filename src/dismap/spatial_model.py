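"""Likelihood and prior kernels for the hierarchical Poisson-CAR model.

The model for the age-adjusted count y*_ir in county i and racial group r
(x1 = 1 for the focal group, x2 = 1 for counties in the lower deprivation
quintile) is

    y*_ir ~ Poisson(n_ir * lambda_ir)
    log lambda_ir = beta0 + beta1*x1 + beta2*x2 + beta3*x1*x2
                    + theta_ir + phi_ir

with exchangeable heterogeneity theta_ir ~ N(0, tau_h) and, per racial
group, an intrinsic (improper) conditional autoregressive field phi over
the county border graph with variance-scale parameter tau_b (reference
group) or tau_c (focal group). Fixed-effect priors are N(0, 1000) for
beta1..beta3 and flat for beta0; the standard deviations sqrt(tau_h),
sqrt(tau_b), sqrt(tau_c) carry Uniform(0, 100) priors by default.

Because the age adjustment produces non-integer counts, the Poisson
log-likelihood uses the continuous gamma-function kernel
y*log(mu) - mu - logGamma(y* + 1), valid for any real y* >= 0 and equal to
the ordinary log-mass at integers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import gammaln

from .data_model import AdjacencyStructure

__all__ = [
    "ModelState",
    "ModelSpec",
    "PriorConfig",
    "linear_predictor",
    "poisson_loglik",
    "icar_log_kernel",
    "icar_rank",
    "log_prior",
]

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class ModelSpec:
    """Which terms of the full model are active.

    The full model has all five switched on; the reduced models used for
    DIC comparison drop the interaction (and optionally the deprivation
    indicator), and the oracle configurations drop the random effects.
    """

    include_race: bool = True
    include_adi: bool = True
    include_interaction: bool = True
    include_theta: bool = True
    include_phi: bool = True

    def __post_init__(self) -> None:
        if self.include_interaction and not (self.include_race and self.include_adi):
            raise ValueError("interaction term requires both race and ADI terms")

    @property
    def n_fixed(self) -> int:
        return 1 + self.include_race + self.include_adi + self.include_interaction


@dataclass(frozen=True)
class PriorConfig:
    """Prior families and hyperparameters; defaults are the study priors.

    ``beta_var`` is the common N(0, var) variance for beta1..beta3; beta0 is
    flat unless ``beta0_var`` is set. Standard deviations take either a
    Uniform(sd_lower, sd_upper) prior or, for sensitivity reruns, a
    half-normal with scale ``sd_halfnormal_scale``.
    """

    beta_var: float = 1000.0
    beta0_var: float | None = None   # None = improper flat prior
    sd_prior: str = "uniform"        # "uniform" | "halfnormal"
    sd_lower: float = 0.0
    sd_upper: float = 100.0
    sd_halfnormal_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.sd_prior not in {"uniform", "halfnormal"}:
            raise ValueError(f"unknown sd prior family {self.sd_prior!r}")
        if not 0 <= self.sd_lower < self.sd_upper:
            raise ValueError("require 0 <= sd_lower < sd_upper")

    def sd_log_density(self, sd: float) -> float:
        """Log prior density of one standard deviation (on the SD scale)."""
        if self.sd_prior == "uniform":
            if self.sd_lower < sd < self.sd_upper:
                return 0.0
            return -np.inf
        if sd <= 0:
            return -np.inf
        return -0.5 * sd**2 / self.sd_halfnormal_scale**2

    @classmethod
    def from_dict(cls, d: dict) -> "PriorConfig":
        return cls(**d)


@dataclass(frozen=True)
class ModelState:
    """All parameters at one MCMC iteration.

    ``theta`` and ``phi`` have shape (I, R); tau parameters are variances
    (the priors are placed on their square roots). For single-race datasets
    the second column of phi and tau_c are inert.
    """

    beta0: float
    beta1: float
    beta2: float
    beta3: float
    theta: np.ndarray
    phi: np.ndarray
    tau_h: float
    tau_b: float
    tau_c: float

    def __post_init__(self) -> None:
        for name in ("tau_h", "tau_b", "tau_c"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def zeros(cls, n_counties: int, n_races: int, **overrides) -> "ModelState":
        base = dict(
            beta0=0.0, beta1=0.0, beta2=0.0, beta3=0.0,
            theta=np.zeros((n_counties, n_races)),
            phi=np.zeros((n_counties, n_races)),
            tau_h=1.0, tau_b=1.0, tau_c=1.0,
        )
        base.update(overrides)
        return cls(**base)

    def replace(self, **changes) -> "ModelState":
        return replace(self, **changes)


def linear_predictor(state: ModelState, x2: np.ndarray, race_indicator: np.ndarray,
                     spec: ModelSpec = ModelSpec()) -> np.ndarray:
    """Rate surface lambda_ir = exp(eta_ir) on the (county, race) grid."""
    x1 = np.asarray(race_indicator, dtype=float)
    x2col = np.asarray(x2, dtype=float).reshape(-1, 1)
    eta = np.full_like(x1, state.beta0, dtype=float)
    if spec.include_race:
        eta = eta + state.beta1 * x1
    if spec.include_adi:
        eta = eta + state.beta2 * x2col
    if spec.include_interaction:
        eta = eta + state.beta3 * x1 * x2col
    if spec.include_theta:
        eta = eta + state.theta
    if spec.include_phi:
        eta = eta + state.phi
    if not np.all(np.isfinite(eta)) or np.any(np.abs(eta) > 700):
        bad = np.argwhere(~np.isfinite(eta) | (np.abs(eta) > 700))[0]
        raise FloatingPointError(
            f"non-finite or overflowing linear predictor at cell "
            f"(county={bad[0]}, race={bad[1]})"
        )
    return np.exp(eta)


def poisson_loglik(y_star: np.ndarray, at_risk: np.ndarray,
                   rate: np.ndarray) -> float:
    """Continuous-Poisson log-likelihood of the adjusted counts.

    sum_ir [ y* log(n*lambda) - n*lambda - logGamma(y* + 1) ]; matches the
    ordinary Poisson log-mass when y* is an integer.
    """
    y = np.asarray(y_star, dtype=float)
    if np.any(y < 0):
        raise ValueError("adjusted counts must be non-negative")
    mu = np.asarray(at_risk, dtype=float) * np.asarray(rate, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(mu), 0.0)
    return float(np.sum(term - mu - gammaln(y + 1.0)))


def icar_log_kernel(phi_one_race: np.ndarray, tau: float,
                    adjacency: AdjacencyStructure) -> float:
    """Pairwise-difference intrinsic CAR log-density, up to a constant.

    -(1/(2 tau)) * sum over borders (i, j) of (phi_i - phi_j)^2; tau plays
    the role of a conditional-variance scale (larger tau = rougher field).
    The density is improper: constant shifts of phi (per connected
    component) are free directions, which is why the sampler pins each
    field to sum to zero.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    phi = np.asarray(phi_one_race, dtype=float)
    if phi.shape != (adjacency.n_counties,):
        raise ValueError("phi length must equal the county count")
    if not adjacency.edges:
        return 0.0
    e = np.asarray(adjacency.edges)
    diffs = phi[e[:, 0]] - phi[e[:, 1]]
    return float(-np.sum(diffs**2) / (2.0 * tau))


def icar_rank(adjacency: AdjacencyStructure) -> int:
    """Rank of the ICAR precision (Laplacian): counties minus components."""
    return adjacency.n_counties - adjacency.n_components


def log_prior(state: ModelState, prior: PriorConfig,
              adjacency: AdjacencyStructure,
              spec: ModelSpec = ModelSpec()) -> float:
    """Joint log prior of a model state, up to additive constants.

    Sums the active fixed-effect normal log-densities (beta0 contributes
    nothing under the flat default), full N(0, tau_h) log-densities for
    theta, the pairwise ICAR kernel for each racial field, and the SD
    priors for the active variance parameters (zero inside the uniform
    support, -inf outside — an out-of-range SD marks the state rejected
    rather than raising).
    """
    lp = 0.0
    if prior.beta0_var is not None:
        lp += -0.5 * (_LOG2PI + np.log(prior.beta0_var)) \
            - 0.5 * state.beta0**2 / prior.beta0_var
    active = []
    if spec.include_race:
        active.append(state.beta1)
    if spec.include_adi:
        active.append(state.beta2)
    if spec.include_interaction:
        active.append(state.beta3)
    for b in active:
        lp += -0.5 * (_LOG2PI + np.log(prior.beta_var)) - 0.5 * b**2 / prior.beta_var
    n_races = state.theta.shape[1]
    if spec.include_theta:
        lp += state.theta.size * (-0.5 * (_LOG2PI + np.log(state.tau_h)))
        lp += -0.5 * float(np.sum(state.theta**2)) / state.tau_h
        lp += prior.sd_log_density(float(np.sqrt(state.tau_h)))
    if spec.include_phi:
        taus = (state.tau_b, state.tau_c)
        for r in range(n_races):
            lp += icar_log_kernel(state.phi[:, r], taus[r], adjacency)
            lp += prior.sd_log_density(float(np.sqrt(taus[r])))
    return float(lp)
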