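"""Derived estimands: rate ratios, posterior summaries, surfaces and DIC.

Three families of disparity estimands are computed per retained draw and
then summarized (ratios of summaries would not yield valid credible
intervals for these nonlinear functionals):

* the overall rate ratio  lam_bar_1 / lam_bar_0, where lam_bar_r is the
  population-weighted statewide average rate sum_i n_ir lam_ir / sum_i n_ir;
* the county rate ratio  lam_i1 / lam_i0 (focal vs reference group); and
* the within-race ratio  lam_i1 / lam_bar_1 (county vs statewide focal
  average).

Credible intervals are equal-tailed 2.5%/97.5% posterior quantiles with
linear interpolation; a county is flagged when its interval lies entirely
below 1. Model adequacy uses the deviance information criterion with the
cell-level log-rates as the focus: DIC = D_bar + pD with
pD = D_bar - D_hat, D_hat evaluated at the posterior mean of log lambda.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import IncidenceDataset
from .mcmc import PosteriorSamples
from .spatial_model import poisson_loglik
from .standardization import age_adjust_counts

__all__ = [
    "RateRatioSummary",
    "DICResult",
    "rate_surface_draws",
    "overall_rate_ratio_draws",
    "county_rate_ratio_draws",
    "within_race_ratio_draws",
    "summarize",
    "count_flagged_counties",
    "heterogeneity_surface",
    "dic",
    "dic_preference",
    "parameter_summary_table",
    "county_table",
]


@dataclass(frozen=True)
class RateRatioSummary:
    """Posterior mean/SD and equal-tailed 95% interval for one estimand."""

    label: str
    mean: float
    sd: float
    lower: float
    upper: float
    excludes_one: bool


@dataclass(frozen=True)
class DICResult:
    """Deviance information criterion decomposition."""

    mean_deviance: float
    p_d: float

    @property
    def dic(self) -> float:
        return self.mean_deviance + self.p_d


def rate_surface_draws(samples: PosteriorSamples,
                       dataset: IncidenceDataset) -> np.ndarray:
    """Reconstruct lambda_ir for every retained draw, shape (draws, I, R)."""
    x1 = dataset.race_indicator()
    x2 = dataset.x2.astype(float)[:, None]
    beta = samples.beta.reshape(-1, 4)
    theta = samples.theta.reshape(-1, *samples.theta.shape[2:])
    phi = samples.phi.reshape(-1, *samples.phi.shape[2:])
    eta = (
        beta[:, 0, None, None]
        + beta[:, 1, None, None] * x1
        + beta[:, 2, None, None] * x2
        + beta[:, 3, None, None] * (x1 * x2)
        + theta
        + phi
    )
    return np.exp(eta)


def _lambda_draws(samples, dataset=None) -> np.ndarray:
    if isinstance(samples, PosteriorSamples):
        if dataset is None:
            raise ValueError("dataset required to reconstruct rate surfaces")
        return rate_surface_draws(samples, dataset)
    lam = np.asarray(samples, dtype=float)
    if lam.ndim == 2:  # a single draw
        lam = lam[None]
    return lam


def _weighted_means(lam: np.ndarray, at_risk: np.ndarray) -> np.ndarray:
    n = np.asarray(at_risk, dtype=float)
    if np.any(n.sum(axis=0) <= 0):
        raise ValueError("zero at-risk population in a racial group")
    return np.einsum("dir,ir->dr", lam, n) / n.sum(axis=0)


def overall_rate_ratio_draws(samples, at_risk=None, dataset=None) -> np.ndarray:
    """Per-draw overall rate ratio lam_bar_1 / lam_bar_0."""
    if isinstance(samples, PosteriorSamples) and at_risk is None:
        at_risk = dataset.at_risk
    lam = _lambda_draws(samples, dataset)
    bar = _weighted_means(lam, at_risk)
    return bar[:, 1] / bar[:, 0]


def county_rate_ratio_draws(samples, dataset=None) -> np.ndarray:
    """Per-draw county-level rate ratios lam_i1 / lam_i0, shape (draws, I)."""
    lam = _lambda_draws(samples, dataset)
    return lam[:, :, 1] / lam[:, :, 0]


def within_race_ratio_draws(samples, at_risk=None, dataset=None) -> np.ndarray:
    """Per-draw within-focal-group ratios lam_i1 / lam_bar_1."""
    if isinstance(samples, PosteriorSamples) and at_risk is None:
        at_risk = dataset.at_risk
    lam = _lambda_draws(samples, dataset)
    r_focal = lam.shape[2] - 1
    bar = _weighted_means(lam, at_risk)[:, r_focal]
    return lam[:, :, r_focal] / bar[:, None]


def summarize(draws, label: str = "") -> RateRatioSummary:
    """Posterior mean, SD and equal-tailed 95% interval of scalar draws."""
    d = np.asarray(draws, dtype=float).ravel()
    if d.size < 2:
        raise ValueError("need at least two draws to summarize")
    if d.size < 100:
        warnings.warn("fewer than 100 draws; interval endpoints are imprecise")
    lower, upper = np.quantile(d, [0.025, 0.975], method="linear")
    return RateRatioSummary(
        label=label,
        mean=float(d.mean()),
        sd=float(d.std(ddof=1)),
        lower=float(lower),
        upper=float(upper),
        excludes_one=bool(upper < 1.0 or lower > 1.0),
    )


def count_flagged_counties(summaries) -> int:
    """Counties whose 95% interval lies entirely below 1 (upper < 1)."""
    return int(sum(1 for s in summaries if s.upper < 1.0))


def heterogeneity_surface(samples: PosteriorSamples) -> dict[str, np.ndarray]:
    """Posterior heterogeneity surfaces exp(theta + phi) per (county, race).

    ``mean_exp`` averages the exponentiated sums over draws (the labeled
    default); ``exp_mean`` exponentiates the posterior-average sum — both
    are exported since map captions are ambiguous between the two readings.
    """
    total = samples.theta + samples.phi  # (chains, draws, I, R)
    flat = total.reshape(-1, *total.shape[2:])
    return {
        "mean_exp": np.exp(flat).mean(axis=0),
        "exp_mean": np.exp(flat.mean(axis=0)),
    }


def dic(samples: PosteriorSamples, dataset: IncidenceDataset) -> DICResult:
    """DIC with the cell-level log-rate surface as the focus."""
    y = age_adjust_counts(dataset, None).y_star
    n = dataset.at_risk
    lam = rate_surface_draws(samples, dataset)
    if lam.shape[0] < 100:
        warnings.warn("fewer than 100 draws; DIC estimate is imprecise")
    deviances = np.array(
        [-2.0 * poisson_loglik(y, n, lam[d]) for d in range(lam.shape[0])]
    )
    mean_dev = float(deviances.mean())
    lam_hat = np.exp(np.log(lam).mean(axis=0))
    dev_hat = -2.0 * poisson_loglik(y, n, lam_hat)
    p_d = mean_dev - dev_hat
    if p_d < -1e-8:
        warnings.warn(f"negative effective parameter count pD = {p_d:.3f}")
    result = DICResult(mean_deviance=mean_dev, p_d=float(p_d))
    if not np.isfinite(result.dic):
        raise ValueError("non-finite DIC")
    return result


def dic_preference(dic_a: float, dic_b: float, threshold: float = 2.0) -> str:
    """Model-choice verdict under the greater-than-2 DIC difference rule."""
    if abs(dic_a - dic_b) <= threshold:
        return "no preference"
    return "model_a" if dic_a < dic_b else "model_b"


def parameter_summary_table(samples: PosteriorSamples) -> pd.DataFrame:
    """Posterior mean/SD/95% interval per scalar model parameter."""
    rows = []
    for name in samples.scalar_names():
        s = summarize(samples.named(name), label=name)
        rows.append((name, s.mean, s.sd, s.lower, s.upper))
    return pd.DataFrame(
        rows, columns=["parameter", "mean", "sd", "lower_2.5", "upper_97.5"]
    )


def county_table(samples: PosteriorSamples, dataset: IncidenceDataset,
                 quintile_labels=None) -> pd.DataFrame:
    """Per-county rate-ratio summary (focal-vs-reference and within-race)."""
    rr = county_rate_ratio_draws(samples, dataset)
    wr = within_race_ratio_draws(samples, dataset=dataset)
    if quintile_labels is None:
        from .standardization import classify_adi

        quintile_labels = classify_adi(dataset.adi_score).labels
    rows = []
    for i, county in enumerate(dataset.counties):
        a = summarize(rr[:, i], label=county)
        b = summarize(wr[:, i], label=county)
        rows.append(
            (county, quintile_labels[i], a.mean, a.lower, a.upper,
             a.excludes_one, b.mean, b.lower, b.upper)
        )
    return pd.DataFrame(
        rows,
        columns=[
            "county", "quintile", "rr_mean", "rr_lower", "rr_upper",
            "rr_excludes_one", "within_race_mean", "within_race_lower",
            "within_race_upper",
        ],
    )
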