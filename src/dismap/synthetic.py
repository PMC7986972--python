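"""Synthetic study-region generator with recorded ground truth.

Data are drawn from exactly the generative structure the hierarchical
model assumes: county deprivation scores are sampled and classified into
quintiles, exchangeable heterogeneity is N(0, tau_h), each racial group
gets an intrinsic CAR spatial field on the county border graph, cell rates
follow the log-linear predictor, and age-stratified counts are Poisson
splits of the expected (county, race) totals across an increasing
incidence-by-age profile. Defaults emulate the New Mexico study region:
the packaged 33-county border graph, two racial groups, fifteen 5-year age
groups from 15-19 to 85+, a focal/reference disparity of log(0.384), and
random-effect standard deviations of the magnitude the model reports there
(0.07 exchangeable; 0.143 and 0.567 for the reference and focal spatial
fields).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .data_model import (
    AGE_LABELS_15,
    AdjacencyStructure,
    IncidenceDataset,
    nm_adjacency_fixture,
)
from .standardization import classify_adi

__all__ = ["GeneratorConfig", "SyntheticTruth", "sample_icar_field", "generate"]

#: 2010-style US female age distribution (15+) over the fifteen groups.
DEFAULT_STD_WEIGHTS = np.array(
    [0.086, 0.085, 0.082, 0.079, 0.081, 0.084, 0.089, 0.087,
     0.079, 0.068, 0.052, 0.041, 0.034, 0.029, 0.024]
)

#: Relative incidence-by-age profile (rises steeply to a plateau past 60),
#: used only to split expected cell counts across age groups.
DEFAULT_AGE_MULTIPLIERS = np.array(
    [0.001, 0.015, 0.08, 0.25, 0.6, 1.2, 1.9, 2.2,
     2.6, 3.2, 3.7, 3.9, 3.8, 3.4, 2.9]
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Generating parameters for one synthetic study region.

    ``beta0`` is the log baseline rate per at-risk woman over the study
    window; ``beta1`` the focal-group log rate ratio; ``beta2``/``beta3``
    the deprivation main effect and interaction. ``sd_h``, ``sd_b``,
    ``sd_c`` are the standard deviations of the exchangeable and the two
    race-specific spatial fields (zero disables a component). ``at_risk``
    gives per-(county, race) denominators: a (reference, focal) pair of
    scalars applied to every county, or a full (I, 2) table.
    """

    adjacency: AdjacencyStructure = field(default_factory=nm_adjacency_fixture)
    age_labels: tuple[str, ...] = tuple(AGE_LABELS_15)
    beta0: float = -7.0
    beta1: float = float(np.log(0.384))
    beta2: float = 0.229
    beta3: float = -0.303
    sd_h: float = 0.07
    sd_b: float = 0.143
    sd_c: float = 0.567
    at_risk: tuple[float, float] | np.ndarray = (11_175, 2_274)
    std_weights: np.ndarray = field(
        default_factory=lambda: DEFAULT_STD_WEIGHTS.copy()
    )
    age_multipliers: np.ndarray = field(
        default_factory=lambda: DEFAULT_AGE_MULTIPLIERS.copy()
    )
    adi_mean: float = 110.0
    adi_sd: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sd_h", "sd_b", "sd_c"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if len(self.std_weights) != len(self.age_labels):
            raise ValueError("std_weights length must match age groups")
        if len(self.age_multipliers) != len(self.age_labels):
            raise ValueError("age_multipliers length must match age groups")

    def at_risk_table(self) -> np.ndarray:
        I = self.adjacency.n_counties
        arr = np.asarray(self.at_risk, dtype=float)
        if arr.shape == (2,):
            arr = np.tile(arr, (I, 1))
        if arr.shape != (I, 2):
            raise ValueError(f"at_risk must be a pair or an ({I}, 2) table")
        if np.any(arr < 1):
            raise ValueError("at-risk sizes must be >= 1")
        return arr


@dataclass(frozen=True)
class SyntheticTruth:
    """Generating parameters and realized latent surfaces for one draw."""

    config: GeneratorConfig
    adi_score: np.ndarray
    x2: np.ndarray
    theta: np.ndarray          # (I, 2)
    phi: np.ndarray            # (I, 2)
    rate_surface: np.ndarray   # lambda, (I, 2)
    overall_rate_ratio: float

    def to_json(self, path) -> None:
        cfg = self.config
        payload = {
            "beta": [cfg.beta0, cfg.beta1, cfg.beta2, cfg.beta3],
            "sd": [cfg.sd_h, cfg.sd_b, cfg.sd_c],
            "seed": cfg.seed,
            "adi_score": self.adi_score.tolist(),
            "x2": self.x2.tolist(),
            "theta": self.theta.tolist(),
            "phi": self.phi.tolist(),
            "rate_surface": self.rate_surface.tolist(),
            "overall_rate_ratio": self.overall_rate_ratio,
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def sample_icar_field(tau: float, adjacency: AdjacencyStructure, rng) -> np.ndarray:
    """Draw an intrinsic CAR field restricted to its proper subspace.

    The ICAR density is Gaussian with precision L/tau (L the graph
    Laplacian) on the subspace orthogonal to the per-component constants;
    the draw has covariance tau * pinv(L) and sums to zero within each
    connected component. ``tau = 0`` returns the zero field.
    """
    if tau < 0:
        raise ValueError("tau must be non-negative")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    n = adjacency.n_counties
    if tau == 0 or n == 0:
        return np.zeros(n)
    evals, evecs = np.linalg.eigh(adjacency.laplacian())
    keep = evals > 1e-9 * max(evals.max(), 1.0)
    z = rng.standard_normal(int(keep.sum()))
    field_ = evecs[:, keep] @ (z * np.sqrt(tau / evals[keep]))
    # exact per-component recentering against floating-point drift
    for k in range(adjacency.n_components):
        comp = adjacency.component_labels == k
        field_[comp] -= field_[comp].mean()
    return field_


def generate(config: GeneratorConfig | None = None,
             seed: int | None = None) -> tuple[IncidenceDataset, SyntheticTruth]:
    """Sample one synthetic dataset and its ground truth.

    Deterministic given (config, seed); ``seed`` overrides ``config.seed``.
    """
    config = config or GeneratorConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    adj = config.adjacency
    I = adj.n_counties
    A = len(config.age_labels)

    adi = rng.normal(config.adi_mean, config.adi_sd, size=I)
    x2 = classify_adi(adi).x2

    theta = rng.normal(0.0, config.sd_h, size=(I, 2)) if config.sd_h > 0 \
        else np.zeros((I, 2))
    phi = np.column_stack([
        sample_icar_field(config.sd_b**2, adj, rng),
        sample_icar_field(config.sd_c**2, adj, rng),
    ])

    x1 = np.broadcast_to(np.array([0.0, 1.0]), (I, 2))
    eta = (
        config.beta0
        + config.beta1 * x1
        + config.beta2 * x2[:, None]
        + config.beta3 * x1 * x2[:, None]
        + theta
        + phi
    )
    lam = np.exp(eta)
    n = config.at_risk_table()
    mu = n * lam
    # lambda is the rate of the age-ADJUSTED count, so the age shares are
    # scaled to make the standard-weighted expectation equal n*lambda:
    # sum_a pi_a * s_a = 1, hence E[y*] = n*lambda exactly.
    weights_n = np.asarray(config.std_weights, dtype=float)
    weights_n = weights_n / weights_n.sum()
    shares = config.age_multipliers * weights_n
    shares = shares / (weights_n @ shares)
    mu_age = mu[:, :, None] * shares[None, None, :]
    if np.any(mu_age > 1e12):
        raise ValueError("expected counts overflow; lower beta0 or at-risk sizes")
    counts = rng.poisson(mu_age)

    weights = np.asarray(config.std_weights, dtype=float)
    weights = weights / weights.sum()
    dataset = IncidenceDataset(
        counties=adj.counties,
        races=(0, 1),
        age_labels=tuple(config.age_labels),
        counts=counts,
        at_risk=n.astype(int),
        std_weights=weights,
        adi_score=adi,
        x2=x2,
        adjacency=adj,
    )
    bar = (n * lam).sum(axis=0) / n.sum(axis=0)
    truth = SyntheticTruth(
        config=config,
        adi_score=adi,
        x2=x2,
        theta=theta,
        phi=phi,
        rate_surface=lam,
        overall_rate_ratio=float(bar[1] / bar[0]),
    )
    return dataset, truth
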