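"""Metropolis-within-Gibbs posterior simulation for the Poisson-CAR model.

Each sweep updates, in order: the fixed-effect block (adaptive random walk
on each coordinate), every exchangeable effect theta_ir (a single
vectorized elementwise Metropolis step — the theta full conditionals are
mutually independent), every spatial effect phi_ir (elementwise Metropolis
over graph-coloring classes, so that no two simultaneously updated
counties are neighbors), a per-race, per-component recentering of phi to
sum to zero, and log-scale random walks on the three standard deviations
with explicit prior-support rejection. Proposal scales adapt toward a 0.44
acceptance rate during burn-in only, and are frozen afterwards so the
chain targets the correct stationary distribution.

The intrinsic CAR field's conditional for its scale parameter includes the
tau^{-rank/2} normalizing factor (rank = counties minus connected
components); the pairwise kernel alone is flat in that direction and would
let the scale drift.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .data_model import IncidenceDataset
from .spatial_model import (
    ModelSpec,
    ModelState,
    PriorConfig,
    icar_rank,
    linear_predictor,
    log_prior,
    poisson_loglik,
)
from .standardization import age_adjust_counts

__all__ = ["ChainConfig", "PosteriorSamples", "run_chain", "fit", "gelman_rubin"]


@dataclass(frozen=True)
class ChainConfig:
    """MCMC run protocol.

    The default protocol is 3 chains, thinned to every fiftieth post-burn-in
    sweep, retaining 20,000 draws per chain (60,000 total); tests and the
    bundled examples scale ``n_iter``/``thin`` down. ``n_iter`` counts
    post-burn-in sweeps and must be a multiple of ``thin``; retained sweeps
    are burn_in + thin, burn_in + 2*thin, ...
    """

    n_chains: int = 3
    burn_in: int = 10_000
    n_iter: int = 1_000_000
    thin: int = 50
    base_seed: int = 0
    adapt_interval: int = 50
    target_accept: float = 0.44

    def __post_init__(self) -> None:
        if self.n_chains < 1 or self.thin < 1 or self.burn_in < 0 or self.n_iter < 0:
            raise ValueError("invalid chain configuration")
        if self.n_iter % self.thin != 0:
            raise ValueError("n_iter must be a multiple of thin")

    @property
    def retained_per_chain(self) -> int:
        return self.n_iter // self.thin

    @property
    def total_retained(self) -> int:
        return self.n_chains * self.retained_per_chain

    @property
    def retained_iterations(self) -> np.ndarray:
        """Post-burn-in sweep indices that are retained."""
        return self.burn_in + self.thin * np.arange(1, self.retained_per_chain + 1)


@dataclass
class PosteriorSamples:
    """Retained draws across chains plus run metadata.

    ``beta`` is (chains, draws, 4) in the order beta0..beta3 (inactive
    coefficients stay at zero); ``theta``/``phi`` are (chains, draws, I, R);
    ``sd`` is (chains, draws, 3) holding sqrt(tau_h), sqrt(tau_b),
    sqrt(tau_c). ``log_post`` is the log posterior kernel at each retained
    draw.
    """

    beta: np.ndarray
    theta: np.ndarray
    phi: np.ndarray
    sd: np.ndarray
    log_post: np.ndarray
    config: ChainConfig
    spec: ModelSpec
    counties: tuple[str, ...]
    races: tuple[int, ...]
    diagnostics: dict = field(default_factory=dict)

    SD_NAMES = ("sd_h", "sd_b", "sd_c")

    @property
    def n_chains(self) -> int:
        return self.beta.shape[0]

    @property
    def n_draws_per_chain(self) -> int:
        return self.beta.shape[1]

    @property
    def n_draws(self) -> int:
        return self.n_chains * self.n_draws_per_chain

    def named(self, parameter: str) -> np.ndarray:
        """Draws for one named scalar parameter, shape (chains, draws)."""
        if parameter.startswith("beta"):
            return self.beta[:, :, int(parameter[4:])]
        if parameter in self.SD_NAMES:
            return self.sd[:, :, self.SD_NAMES.index(parameter)]
        for block_name in ("theta", "phi"):
            if parameter.startswith(block_name + "["):
                inner = parameter[len(block_name) + 1 : -1]
                i, r = (int(t) for t in inner.split(","))
                return getattr(self, block_name)[:, :, i, r]
        raise KeyError(f"unknown parameter {parameter!r}")

    def scalar_names(self) -> list[str]:
        names = ["beta0"]
        if self.spec.include_race:
            names.append("beta1")
        if self.spec.include_adi:
            names.append("beta2")
        if self.spec.include_interaction:
            names.append("beta3")
        if self.spec.include_theta:
            names.append("sd_h")
        if self.spec.include_phi:
            names.append("sd_b")
            if len(self.races) > 1:
                names.append("sd_c")
        return names

    def to_frame(self):
        """Flat (chain, iter, parameter, value) records of all draws."""
        import pandas as pd

        I, R = self.theta.shape[2], self.theta.shape[3]
        names = ["beta0", "beta1", "beta2", "beta3"]
        names += [f"theta[{i},{r}]" for i in range(I) for r in range(R)]
        names += [f"phi[{i},{r}]" for i in range(I) for r in range(R)]
        names += list(self.SD_NAMES)
        flat = np.concatenate(
            [
                self.beta,
                self.theta.reshape(*self.theta.shape[:2], -1),
                self.phi.reshape(*self.phi.shape[:2], -1),
                self.sd,
            ],
            axis=2,
        )
        iters = self.config.retained_iterations
        records = []
        for c in range(self.n_chains):
            frame = pd.DataFrame(flat[c], columns=names)
            frame.insert(0, "iter", iters[: self.n_draws_per_chain])
            frame.insert(0, "chain", c)
            records.append(frame.melt(id_vars=["chain", "iter"],
                                      var_name="parameter", value_name="value"))
        return pd.concat(records, ignore_index=True)


def _initial_betas(y_star, n, x1, x2, spec: ModelSpec) -> np.ndarray:
    """Fixed-effects Poisson MLE via GLM (IRLS) on the adjusted counts."""
    beta = np.zeros(4)
    total_y, total_n = float(y_star.sum()), float(n.sum())
    beta[0] = np.log(max(total_y, 0.5) / total_n)
    cols = [np.ones(y_star.size)]
    active = [0]
    if spec.include_race:
        cols.append(x1.ravel())
        active.append(1)
    if spec.include_adi:
        cols.append(np.broadcast_to(x2[:, None], x1.shape).ravel().astype(float))
        active.append(2)
    if spec.include_interaction:
        cols.append((x1 * x2[:, None]).ravel())
        active.append(3)
    if len(cols) > 1 and total_y > 0:
        try:
            import statsmodels.api as sm

            res = sm.GLM(
                y_star.ravel(),
                np.column_stack(cols),
                family=sm.families.Poisson(),
                offset=np.log(n.ravel().astype(float)),
            ).fit()
            if np.all(np.isfinite(res.params)) and np.all(np.abs(res.params) < 50):
                beta[:] = 0.0
                beta[active] = res.params
        except Exception:  # perfect separation / all-zero strata: keep fallback
            pass
    return beta


class _ChainSampler:
    """One chain's state and sweep kernel; see module docstring for the order."""

    def __init__(self, dataset: IncidenceDataset, prior: PriorConfig,
                 config: ChainConfig, spec: ModelSpec, chain_index: int):
        self.dataset = dataset
        self.prior = prior
        self.config = config
        self.spec = spec
        self.rng = np.random.default_rng(
            np.random.SeedSequence([int(config.base_seed), int(chain_index)])
        )

        self.y = age_adjust_counts(dataset, None).y_star  # (I, R)
        self.n = dataset.at_risk.astype(float)
        self.x1 = dataset.race_indicator()
        self.x2 = dataset.x2.astype(float)
        self.I, self.R = self.y.shape
        if self.y.sum() == 0:
            warnings.warn("all adjusted counts are zero; posterior is prior-driven")

        adj = dataset.adjacency
        self.adjacency = adj
        self.W = np.zeros((self.I, self.I))
        for i, j in adj.edges:
            self.W[i, j] = self.W[j, i] = 1.0
        self.degree = self.W.sum(axis=1)
        self.laplacian = np.diag(self.degree) - self.W
        self.rank = icar_rank(adj)
        coloring = nx.greedy_color(adj.to_graph())
        classes: dict[int, list[int]] = {}
        for node, color in coloring.items():
            classes.setdefault(color, []).append(node)
        self.color_classes = [np.array(sorted(v)) for _, v in sorted(classes.items())]
        self.components = [
            np.flatnonzero(adj.component_labels == k)
            for k in range(adj.n_components)
        ]

        # state
        self.beta = _initial_betas(self.y, self.n, self.x1, self.x2, spec)
        self.theta = np.zeros((self.I, self.R))
        self.phi = np.zeros((self.I, self.R))
        self.sd = np.array([0.5, 0.5, 0.5])  # sqrt tau_h, tau_b, tau_c
        self.mu = self._mu()
        if not np.all(np.isfinite(self.mu)):
            raise RuntimeError("non-finite rate surface at initialization")
        if not np.isfinite(self._log_post()):
            raise RuntimeError("non-finite log posterior at initialization")

        # proposal scales (adapted during burn-in)
        self.beta_scale = np.full(4, 0.1)
        self.theta_scale = 0.5
        self.phi_scale = np.full(self.R, 0.5)
        self.sd_scale = np.full(3, 0.5)
        self._acc = {}
        self._batch = 0

    # -- target pieces ---------------------------------------------------
    def _state(self) -> ModelState:
        return ModelState(
            beta0=self.beta[0], beta1=self.beta[1], beta2=self.beta[2],
            beta3=self.beta[3], theta=self.theta, phi=self.phi,
            tau_h=float(self.sd[0] ** 2), tau_b=float(self.sd[1] ** 2),
            tau_c=float(self.sd[2] ** 2),
        )

    def _mu(self) -> np.ndarray:
        lam = linear_predictor(self._state(), self.x2, self.x1, self.spec)
        return self.n * lam

    def _log_post(self) -> float:
        state = self._state()
        lam = self.mu / self.n
        return poisson_loglik(self.y, self.n, lam) + log_prior(
            state, self.prior, self.adjacency, self.spec
        )

    # -- bookkeeping -----------------------------------------------------
    def _record(self, key: str, accepted: float, proposed: float) -> None:
        acc = self._acc.setdefault(key, [0.0, 0.0])
        acc[0] += accepted
        acc[1] += proposed

    def _adapt(self) -> None:
        self._batch += 1
        step = min(0.5, 1.0 / np.sqrt(self._batch))
        for key, (acc, prop) in self._acc.items():
            if prop == 0:
                continue
            factor = np.exp(step * (acc / prop - self.config.target_accept))
            kind, idx = key
            if kind == "beta":
                self.beta_scale[idx] *= factor
            elif kind == "theta":
                self.theta_scale *= factor
            elif kind == "phi":
                self.phi_scale[idx] *= factor
            elif kind == "sd":
                self.sd_scale[idx] *= factor
        self._acc = {}

    # -- sweep -----------------------------------------------------------
    def _design_column(self, j: int) -> np.ndarray:
        if j == 0:
            return np.ones_like(self.x1)
        if j == 1:
            return self.x1
        if j == 2:
            return np.broadcast_to(self.x2[:, None], self.x1.shape)
        return self.x1 * self.x2[:, None]

    def _active_betas(self) -> list[int]:
        active = [0]
        if self.spec.include_race:
            active.append(1)
        if self.spec.include_adi:
            active.append(2)
        if self.spec.include_interaction:
            active.append(3)
        return active

    def _update_betas(self) -> None:
        for j in self._active_betas():
            db = self.beta_scale[j] * self.rng.standard_normal()
            col = self._design_column(j)
            mu_new = self.mu * np.exp(db * col)
            delta = float(np.sum(self.y * col) * db - np.sum(mu_new - self.mu))
            if j == 0:
                if self.prior.beta0_var is not None:
                    b, v = self.beta[0], self.prior.beta0_var
                    delta += -((b + db) ** 2 - b**2) / (2.0 * v)
            else:
                b = self.beta[j]
                delta += -((b + db) ** 2 - b**2) / (2.0 * self.prior.beta_var)
            accept = np.log(self.rng.uniform()) < delta
            if accept:
                self.beta[j] += db
                self.mu = mu_new
            self._record(("beta", j), float(accept), 1.0)

    def _update_theta(self) -> None:
        tau_h = self.sd[0] ** 2
        d = self.theta_scale * self.rng.standard_normal(self.theta.shape)
        growth = np.exp(d)
        delta = (
            self.y * d
            - self.mu * (growth - 1.0)
            - ((self.theta + d) ** 2 - self.theta**2) / (2.0 * tau_h)
        )
        accept = np.log(self.rng.uniform(size=d.shape)) < delta
        self.theta = np.where(accept, self.theta + d, self.theta)
        self.mu = np.where(accept, self.mu * growth, self.mu)
        self._record(("theta", 0), float(accept.sum()), float(accept.size))

    def _update_phi(self) -> None:
        for r in range(self.R):
            tau = self.sd[1 + r] ** 2
            for cls in self.color_classes:
                w_phi = self.W[cls] @ self.phi[:, r]
                d = self.phi_scale[r] * self.rng.standard_normal(cls.size)
                old = self.phi[cls, r]
                new = old + d
                growth = np.exp(d)
                delta = (
                    self.y[cls, r] * d
                    - self.mu[cls, r] * (growth - 1.0)
                    - (self.degree[cls] * (new**2 - old**2) - 2.0 * d * w_phi)
                    / (2.0 * tau)
                )
                accept = np.log(self.rng.uniform(size=cls.size)) < delta
                self.phi[cls, r] = np.where(accept, new, old)
                self.mu[cls, r] = np.where(
                    accept, self.mu[cls, r] * growth, self.mu[cls, r]
                )
                self._record(("phi", r), float(accept.sum()), float(accept.size))
            # sum-to-zero per connected component
            for comp in self.components:
                shift = self.phi[comp, r].mean()
                if shift != 0.0:
                    self.phi[comp, r] -= shift
                    self.mu[comp, r] *= np.exp(-shift)

    def _update_sd(self, idx: int) -> None:
        s = self.sd[idx]
        dz = self.sd_scale[idx] * self.rng.standard_normal()
        s_new = s * np.exp(dz)
        lp_new = self.prior.sd_log_density(float(s_new))
        if not np.isfinite(lp_new):
            self._record(("sd", idx), 0.0, 1.0)
            return
        if idx == 0:
            ss = float(np.sum(self.theta**2))
            k = self.theta.size  # N(0, s^2) normalization per theta
        else:
            r = idx - 1
            ss = float(self.phi[:, r] @ (self.laplacian @ self.phi[:, r]))
            k = self.rank  # tau^{-rank/2} ICAR normalization
        delta = (
            -k * dz
            - 0.5 * ss * (1.0 / s_new**2 - 1.0 / s**2)
            + lp_new
            - self.prior.sd_log_density(float(s))
            + dz  # log-scale proposal Jacobian
        )
        accept = np.log(self.rng.uniform()) < delta
        if accept:
            self.sd[idx] = s_new
        self._record(("sd", idx), float(accept), 1.0)

    def sweep(self) -> None:
        self._update_betas()
        if self.spec.include_theta:
            self._update_theta()
        if self.spec.include_phi:
            self._update_phi()
        if self.spec.include_theta:
            self._update_sd(0)
        if self.spec.include_phi:
            self._update_sd(1)
            if self.R > 1:
                self._update_sd(2)

    def run(self):
        cfg = self.config
        n_keep = cfg.retained_per_chain
        beta_out = np.empty((n_keep, 4))
        theta_out = np.empty((n_keep, self.I, self.R))
        phi_out = np.empty((n_keep, self.I, self.R))
        sd_out = np.empty((n_keep, 3))
        lp_out = np.empty(n_keep)
        k = 0
        total = cfg.burn_in + cfg.n_iter
        for it in range(1, total + 1):
            self.sweep()
            if it <= cfg.burn_in:
                if it % cfg.adapt_interval == 0:
                    self._adapt()
                if it == cfg.burn_in:
                    self._acc = {}
            elif (it - cfg.burn_in) % cfg.thin == 0:
                beta_out[k] = self.beta
                theta_out[k] = self.theta
                phi_out[k] = self.phi
                sd_out[k] = self.sd
                lp_out[k] = self._log_post()
                k += 1
        assert k == n_keep
        return beta_out, theta_out, phi_out, sd_out, lp_out


def run_chain(dataset: IncidenceDataset, prior_config: PriorConfig,
              chain_config: ChainConfig, chain_index: int,
              model_spec: ModelSpec = ModelSpec()):
    """Run a single chain; deterministic given (base_seed, chain_index)."""
    sampler = _ChainSampler(dataset, prior_config, chain_config, model_spec,
                            chain_index)
    return sampler.run()


def fit(dataset: IncidenceDataset, prior_config: PriorConfig | None = None,
        chain_config: ChainConfig | None = None,
        model_spec: ModelSpec = ModelSpec()) -> PosteriorSamples:
    """Run all chains and bundle retained draws with convergence diagnostics.

    Chain c draws from an independent RNG stream derived from
    (base_seed, c); retained draws are concatenated across chains in the
    returned object, and the classic Gelman-Rubin statistic is recorded per
    scalar parameter when at least two chains with draws are available.
    """
    prior_config = prior_config or PriorConfig()
    chain_config = chain_config or ChainConfig()
    outs = [
        run_chain(dataset, prior_config, chain_config, c, model_spec)
        for c in range(chain_config.n_chains)
    ]
    samples = PosteriorSamples(
        beta=np.stack([o[0] for o in outs]),
        theta=np.stack([o[1] for o in outs]),
        phi=np.stack([o[2] for o in outs]),
        sd=np.stack([o[3] for o in outs]),
        log_post=np.stack([o[4] for o in outs]),
        config=chain_config,
        spec=model_spec,
        counties=dataset.counties,
        races=dataset.races,
    )
    if not np.all(np.isfinite(samples.log_post)):
        raise RuntimeError("non-finite log posterior among retained draws")
    if chain_config.n_chains >= 2 and samples.n_draws_per_chain >= 10:
        samples.diagnostics["gelman_rubin"] = {
            name: gelman_rubin(samples, name) for name in samples.scalar_names()
        }
    return samples


def gelman_rubin(samples: PosteriorSamples, parameter: str) -> float:
    """Classic potential-scale-reduction statistic for one parameter.

    sqrt of (weighted within + between chain variance) over the within-chain
    variance, floored at 1 so that identical chains score exactly 1.0.
    """
    if samples.n_chains < 2:
        raise ValueError("Gelman-Rubin diagnostic requires at least two chains")
    draws = samples.named(parameter)
    n = draws.shape[1]
    if n < 10:
        raise ValueError("need at least 10 draws per chain")
    within = float(np.mean(np.var(draws, axis=1, ddof=1)))
    between_over_n = float(np.var(np.mean(draws, axis=1), ddof=1))
    if within == 0.0:
        return 1.0 if between_over_n == 0.0 else float("inf")
    var_plus = (n - 1) / n * within + between_over_n
    return max(1.0, float(np.sqrt(var_plus / within)))
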