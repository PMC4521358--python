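"""Sampler correctness on conjugate toys, R-hat, DIC, model selection."""

import math

import numpy as np
import pytest

import microdem as md
from microdem.calibration import Chain, DICResult, McmcSettings, dic, run_chain


def normal_logpost(mean, sd):
    def lp(x):
        z = (np.asarray(x) - mean) / sd
        return float(np.sum(-0.5 * z * z - math.log(sd) - 0.5 * math.log(2 * math.pi)))

    return lp


def toy_chain(draws, deviance=None, names=None):
    draws = np.atleast_2d(np.asarray(draws, float))
    if draws.shape[0] == 1:
        draws = draws.T
    if deviance is None:
        deviance = np.zeros(draws.shape[0])
    return Chain(
        draws=draws,
        deviance=np.asarray(deviance, float),
        names=names or [f"x{i}" for i in range(draws.shape[1])],
        accept_rate=0.5,
        seed=0,
        burn_in=0,
    )


class TestSampler:
    def test_conjugate_normal_posterior_mean(self):
        """Posterior mean of a known Normal target is recovered within
        3 Monte-Carlo standard errors."""
        mean, sd = 2.5, 0.7
        settings = McmcSettings(iterations=20_000, burn_in=5_000, n_chains=1, seed=0)
        chain = run_chain(
            normal_logpost(mean, sd), np.array([0.0]), np.array([[-10.0, 10.0]]), settings, seed=5
        )
        draws = chain.draws[:, 0]
        n_eff = len(draws) / (2 * 50)  # crude IACT allowance for a random-walk kernel
        mc_se = sd / math.sqrt(n_eff)
        assert draws.mean() == pytest.approx(mean, abs=3 * mc_se)
        assert draws.std() == pytest.approx(sd, rel=0.25)

    def test_same_seed_identical_chains(self):
        settings = McmcSettings(iterations=2_000, burn_in=500, n_chains=1, seed=0)
        kw = dict(
            logpost=normal_logpost(0.0, 1.0),
            x0=np.array([1.0]),
            bounds=np.array([[-10.0, 10.0]]),
            settings=settings,
            seed=42,
        )
        np.testing.assert_array_equal(run_chain(**kw).draws, run_chain(**kw).draws)

    def test_zero_retained_iterations_rejected(self):
        with pytest.raises(ValueError):
            McmcSettings(iterations=100, burn_in=100)


class TestGelmanRubin:
    def test_same_distribution_chains_converge(self):
        rng = np.random.default_rng(3)
        chains = [toy_chain(rng.normal(0, 1, size=5_000)) for _ in range(4)]
        assert float(md.gelman_rubin(chains)[0]) < 1.05

    def test_separated_chains_flagged(self):
        rng = np.random.default_rng(4)
        c1 = toy_chain(rng.normal(0, 1, size=2_000))
        c2 = toy_chain(rng.normal(100, 1, size=2_000))
        assert float(md.gelman_rubin([c1, c2])[0]) > 10.0

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            md.gelman_rubin([toy_chain(np.random.default_rng(0).normal(size=100))])

    def test_length_one_chains_rejected(self):
        with pytest.raises(ValueError):
            md.gelman_rubin([toy_chain([1.0]), toy_chain([2.0])])


class TestDIC:
    def test_spiegelhalter_formulas(self):
        """Deviances {10,12,14} with D(theta_bar)=9: D_bar=12, p_D=3, DIC=15."""
        chain = toy_chain([0.0, 1.0, 2.0], deviance=[10.0, 12.0, 14.0])
        res = dic([chain], deviance_fn=lambda theta: 9.0)
        assert res.mean_deviance == 12.0
        assert res.p_d == 3.0
        assert res.dic == 15.0

    def test_point_mass_posterior_has_zero_pd(self):
        chain = toy_chain([1.5, 1.5, 1.5], deviance=[7.0, 7.0, 7.0])
        res = dic([chain], deviance_fn=lambda theta: 7.0)
        assert res.p_d == 0.0
        assert res.dic == 7.0

    def test_empty_chains_rejected(self):
        with pytest.raises(ValueError):
            dic([], deviance_fn=lambda theta: 0.0)

    @pytest.mark.parametrize("k", [1, 3])
    def test_effective_parameters_match_dimension(self, k):
        """A Gaussian toy with k free means and diffuse priors has p_D ~ k."""
        rng_data_mean = np.linspace(-1, 1, k)
        sd = 1.0
        lp = normal_logpost(rng_data_mean, sd)
        dev_fn = lambda theta: -2.0 * lp(theta)
        settings = McmcSettings(iterations=120_000 // k, burn_in=20_000 // k, n_chains=1, seed=0)
        chain = run_chain(
            lp,
            rng_data_mean + 0.1,
            np.tile([-50.0, 50.0], (k, 1)),
            settings,
            seed=9 + k,
        )
        res = dic([chain], deviance_fn=dev_fn)
        assert res.p_d == pytest.approx(k, abs=0.5)


class TestSelectModel:
    def make(self, dic_value):
        return DICResult(dic_value, dic_value, 0.0, dic_value)

    def test_nested_comparison_table(self):
        """Deltas +5.2 then -259.1 select the most complex variant with a
        meaningful margin."""
        D = 1000.0
        results = {"v1": self.make(D), "v2": self.make(D + 5.2), "v3": self.make(D + 5.2 - 259.1)}
        table, selected, meaningful = md.select_model(results)
        assert selected == "v3"
        assert meaningful
        np.testing.assert_allclose(
            table["delta_vs_previous"].to_numpy()[1:], [5.2, -259.1], rtol=1e-12
        )

    def test_tie_selects_simplest(self):
        table, selected, meaningful = md.select_model({"v1": self.make(50.0), "v2": self.make(50.0)})
        assert selected == "v1"
        assert not meaningful

    def test_small_margin_not_meaningful(self):
        table, selected, meaningful = md.select_model({"v1": self.make(50.0), "v2": self.make(46.0)})
        assert selected == "v2"
        assert not meaningful
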