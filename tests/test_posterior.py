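import numpy as np
import pytest

from dismap.mcmc import ChainConfig, PosteriorSamples, fit
from dismap.posterior import (
    RateRatioSummary,
    count_flagged_counties,
    county_rate_ratio_draws,
    dic,
    dic_preference,
    heterogeneity_surface,
    overall_rate_ratio_draws,
    summarize,
    within_race_ratio_draws,
)
from dismap.spatial_model import ModelSpec, PriorConfig

from conftest import make_dataset


def _lam(*surfaces):
    """Stack (I, 2) rate surfaces into a (draws, I, 2) array."""
    return np.stack([np.asarray(s, dtype=float) for s in surfaces])


class TestRateRatioDraws:
    def test_identical_surfaces_give_unit_ratio(self):
        # county ratios are 1 whenever the two groups share a surface;
        # the overall ratio is 1 for any n once the group-specific
        # population weightings agree (equal columns of n) or the shared
        # surface is constant across counties
        lam = _lam([[0.01, 0.01], [0.02, 0.02]])
        np.testing.assert_allclose(county_rate_ratio_draws(lam), 1.0)
        n_equal = np.array([[100, 100], [300, 300]])
        np.testing.assert_allclose(overall_rate_ratio_draws(lam, n_equal), 1.0)
        flat = _lam([[0.03, 0.03], [0.03, 0.03]])
        n_any = np.array([[100, 50], [300, 70]])
        np.testing.assert_allclose(overall_rate_ratio_draws(flat, n_any), 1.0)

    def test_single_county_ratio(self):
        lam = _lam([[4.0, 2.0]])
        n = np.array([[10, 10]])
        np.testing.assert_allclose(overall_rate_ratio_draws(lam, n), 0.5)

    def test_population_weighted_overall_ratio(self):
        lam = _lam([[0.02, 0.01], [0.03, 0.02]])
        n = np.array([[200, 100], [200, 300]])
        # focal: (100*.01 + 300*.02)/400 = .0175; ref: (200*.02+200*.03)/400 = .025
        np.testing.assert_allclose(overall_rate_ratio_draws(lam, n), 0.7)

    def test_county_ratios_elementwise(self):
        rng = np.random.default_rng(0)
        lam = rng.uniform(0.01, 0.1, (4, 5, 2))
        got = county_rate_ratio_draws(lam)
        for d in range(4):
            for i in range(5):
                assert got[d, i] == pytest.approx(lam[d, i, 1] / lam[d, i, 0])

    def test_halved_focal_surface(self):
        lam = np.ones((3, 4, 2))
        lam[:, :, 1] = 0.5
        np.testing.assert_allclose(county_rate_ratio_draws(lam), 0.5)

    def test_within_race_all_equal_gives_ones(self):
        lam = _lam(np.full((5, 2), 0.03))
        n = np.full((5, 2), 40)
        np.testing.assert_allclose(within_race_ratio_draws(lam, n), 1.0)

    def test_within_race_two_counties(self):
        lam = _lam([[0.05, 0.01], [0.05, 0.03]])
        n = np.array([[100, 100], [100, 100]])
        np.testing.assert_allclose(within_race_ratio_draws(lam, n)[0],
                                   [0.5, 1.5])

    def test_overall_equals_county_for_single_county(self):
        lam = np.exp(np.random.default_rng(1).normal(-4, 0.2, (50, 1, 2)))
        n = np.array([[123, 45]])
        np.testing.assert_allclose(
            overall_rate_ratio_draws(lam, n),
            county_rate_ratio_draws(lam)[:, 0],
        )

    def test_scale_equivariance(self):
        rng = np.random.default_rng(2)
        lam = rng.uniform(0.01, 0.1, (20, 3, 2))
        n = rng.integers(10, 100, (3, 2))
        c = 2.5
        scaled = lam.copy()
        scaled[:, :, 1] *= c
        np.testing.assert_allclose(
            overall_rate_ratio_draws(scaled, n),
            c * overall_rate_ratio_draws(lam, n),
        )
        np.testing.assert_allclose(
            county_rate_ratio_draws(scaled), c * county_rate_ratio_draws(lam)
        )
        np.testing.assert_allclose(
            within_race_ratio_draws(scaled, n), within_race_ratio_draws(lam, n)
        )

    def test_zero_population_rejected(self):
        lam = np.ones((2, 2, 2))
        with pytest.raises(ValueError, match="at-risk"):
            overall_rate_ratio_draws(lam, np.array([[0, 0], [0, 0]]))


class TestSummarize:
    def test_constant_draws(self):
        s = summarize(np.full(200, 3.25))
        assert (s.mean, s.sd, s.lower, s.upper) == (3.25, 0.0, 3.25, 3.25)

    def test_uniform_grid_quantile_interpolation(self):
        s = summarize(np.arange(1.0, 10001.0))
        assert s.lower == pytest.approx(250.975)
        assert s.upper == pytest.approx(9750.025)

    def test_excludes_one_below(self):
        s = summarize(np.random.default_rng(0).uniform(0.2, 0.8, 500))
        assert s.excludes_one

    def test_straddling_interval_does_not_exclude(self):
        s = summarize(np.random.default_rng(0).uniform(0.5, 1.5, 500))
        assert not s.excludes_one

    def test_quantiles_monotone_in_draw_set(self):
        rng = np.random.default_rng(3)
        draws = rng.normal(1.0, 0.3, 400)
        base = summarize(draws)
        extended = summarize(np.append(draws, draws.max() + 5.0))
        assert extended.lower >= base.lower - 1e-12
        assert extended.upper >= base.upper - 1e-12

    def test_few_draws_warn(self):
        with pytest.warns(UserWarning, match="100"):
            summarize(np.arange(10.0))


def test_count_flagged_counties():
    def s(lo, hi):
        return RateRatioSummary("x", (lo + hi) / 2, 0.1, lo, hi, hi < 1)

    assert count_flagged_counties([s(0.8, 1.2), s(0.9, 1.4)]) == 0
    assert count_flagged_counties([s(0.3, 0.5)] * 4) == 4
    assert count_flagged_counties([s(0.3, 0.9), s(0.5, 1.1), s(0.2, 0.7)]) == 2


class TestHeterogeneitySurface:
    def _samples(self, theta, phi):
        theta = np.asarray(theta, dtype=float)
        n = theta.shape[1]
        cfg = ChainConfig(n_chains=1, burn_in=0, n_iter=n, thin=1)
        return PosteriorSamples(
            beta=np.zeros((1, n, 4)), theta=theta[None].transpose(0, 2, 1, 3),
            phi=np.asarray(phi, dtype=float)[None].transpose(0, 2, 1, 3),
            sd=np.ones((1, n, 3)), log_post=np.zeros((1, n)),
            config=cfg, spec=ModelSpec(), counties=("c0",), races=(0, 1),
        )

    def test_zero_effects_give_unit_surface(self):
        z = np.zeros((1, 100, 2))
        surf = heterogeneity_surface(self._samples(z, z))
        np.testing.assert_allclose(surf["mean_exp"], 1.0)
        np.testing.assert_allclose(surf["exp_mean"], 1.0)

    def test_constant_sum(self):
        theta = np.full((1, 50, 2), 0.3)
        phi = np.full((1, 50, 2), 0.9)
        surf = heterogeneity_surface(self._samples(theta, phi))
        np.testing.assert_allclose(surf["mean_exp"], np.exp(1.2))

    def test_lognormal_mean_identity(self):
        rng = np.random.default_rng(8)
        theta = rng.normal(0.0, 0.5, (1, 200_000, 2))
        phi = np.zeros_like(theta)
        surf = heterogeneity_surface(self._samples(theta, phi))
        np.testing.assert_allclose(surf["mean_exp"], np.exp(0.125), rtol=0.01)
        np.testing.assert_allclose(surf["exp_mean"], 1.0, rtol=0.01)


class TestDic:
    def test_degenerate_posterior_has_zero_pd(self, toy_dataset):
        cfg = ChainConfig(n_chains=1, burn_in=0, n_iter=150, thin=1)
        n = 150
        I, R = 3, 2
        samples = PosteriorSamples(
            beta=np.tile([-3.0, -0.5, 0.0, 0.0], (1, n, 1)),
            theta=np.zeros((1, n, I, R)), phi=np.zeros((1, n, I, R)),
            sd=np.ones((1, n, 3)), log_post=np.zeros((1, n)),
            config=cfg, spec=ModelSpec(), counties=toy_dataset.counties,
            races=(0, 1),
        )
        result = dic(samples, toy_dataset)
        assert result.p_d == pytest.approx(0.0, abs=1e-9)
        assert result.dic == pytest.approx(result.mean_deviance)

    def test_shrinking_draws_toward_plugin_lowers_dic(self, toy_dataset):
        """Contracting the posterior cloud toward its log-scale mean keeps
        the plug-in deviance fixed but lowers the mean deviance (the
        deviance is convex in the log-rates), so pD and DIC both drop."""
        rng = np.random.default_rng(9)
        n, I, R = 200, 3, 2
        cfg = ChainConfig(n_chains=1, burn_in=0, n_iter=n, thin=1)

        def build(theta):
            return PosteriorSamples(
                beta=np.tile([-3.0, -0.5, 0.0, 0.0], (1, n, 1)),
                theta=theta[None], phi=np.zeros((1, n, I, R)),
                sd=np.ones((1, n, 3)), log_post=np.zeros((1, n)),
                config=cfg, spec=ModelSpec(), counties=toy_dataset.counties,
                races=(0, 1),
            )

        theta = rng.normal(0.0, 0.4, (n, I, R))
        center = theta.mean(axis=0, keepdims=True)
        shrunk = center + 0.4 * (theta - center)
        wide, narrow = dic(build(theta), toy_dataset), dic(build(shrunk),
                                                           toy_dataset)
        assert narrow.p_d < wide.p_d
        assert narrow.dic < wide.dic

    @pytest.mark.parametrize(
        "d1, d2, verdict",
        [
            (160.9, 162.4, "no preference"),
            (158.1, 160.9, "model_a"),
            (162.8, 158.1, "model_b"),
        ],
    )
    def test_preference_rule(self, d1, d2, verdict):
        assert dic_preference(d1, d2) == verdict
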