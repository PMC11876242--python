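"""Bayesian inversion: posterior density, sampler, summaries, diagnostics."""

import numpy as np
import pytest
from scipy import stats

from enzkin.inference import (
    ParameterPrior,
    Posterior,
    PriorSpec,
    RateDataset,
    log_posterior,
    run_mcmc,
    split_rhat,
    summarize_posterior,
)
from enzkin.kinetics import mm_rate

S7 = np.array([25.0, 50.0, 100.0, 250.0, 500.0, 750.0, 1000.0])
E_TOTAL = 0.02


def _dataset(K_M=100.0, k_cat=10.0, noise=0.05, seed=0):
    rng = np.random.default_rng(seed)
    v = mm_rate(S7, k_cat * E_TOTAL, K_M)
    v_obs = np.maximum(v * (1 + noise * rng.standard_normal(len(S7))), 0.0)
    return RateDataset(S=S7, v_obs=v_obs, E_total=E_TOTAL)


class TestLogPosterior:
    prior = PriorSpec()

    def test_outside_support_is_minus_inf(self):
        assert log_posterior((0.5, 1.0, 0.1), _dataset(), self.prior) == -np.inf
        assert log_posterior((100.0, 1e5, 0.1), _dataset(), self.prior) == -np.inf
        assert log_posterior((-1.0, 1.0, 0.1), _dataset(), self.prior) == -np.inf

    def test_zero_residual_gaussian_identity(self):
        K_M, k_cat, sd = 100.0, 10.0, 0.3
        v = mm_rate(S7, k_cat * E_TOTAL, K_M)
        data = RateDataset(S=S7, v_obs=v, E_total=E_TOTAL)
        n = len(S7)
        expected_ll = -n * np.log(sd * np.sqrt(2 * np.pi))
        lp = log_posterior((K_M, k_cat, sd), data, self.prior)
        lp_prior = log_posterior((K_M, k_cat, sd), None, self.prior)
        assert lp - lp_prior == pytest.approx(expected_ll)

    def test_matches_termwise_gaussian_densities(self):
        # independent oracle: scipy normal log-pdfs summed term by term
        S = np.array([10.0, 50.0, 200.0, 800.0])
        v_obs = np.array([0.05, 0.1, 0.2, 0.22])
        data = RateDataset(S=S, v_obs=v_obs, E_total=E_TOTAL)
        theta = (120.0, 15.0, 0.03)
        mu = mm_rate(S, theta[1] * E_TOTAL, theta[0])
        oracle = stats.norm.logpdf(v_obs, mu, theta[2]).sum()
        lp = log_posterior(theta, data, self.prior)
        lp_prior = log_posterior(theta, None, self.prior)
        assert lp - lp_prior == pytest.approx(oracle)

    def test_dataset_validation(self):
        with pytest.raises(ValueError):
            RateDataset(S=np.array([1.0, 1.0, 2.0, 3.0]), v_obs=np.zeros(4), E_total=1.0)
        with pytest.raises(ValueError):
            RateDataset(S=S7, v_obs=-np.ones(7), E_total=1.0)


class TestPriors:
    def test_log_uniform_quantiles(self):
        p = ParameterPrior("log-uniform", low=1.0, high=100.0)
        assert p.quantile(0.5) == pytest.approx(10.0)
        assert p.quantile(np.array([0.0, 1.0])) == pytest.approx([1.0, 100.0])

    def test_log_normal_density_matches_scipy(self):
        p = ParameterPrior("log-normal", mean=2.0, sd=0.5)
        x = 1.3
        assert p.log_pdf(x) == pytest.approx(stats.norm.logpdf(x, 2.0, 0.5))

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            ParameterPrior("log-uniform", low=10.0, high=1.0)
        with pytest.raises(ValueError):
            ParameterPrior("gamma", low=1.0, high=2.0)


class TestRunMCMC:
    def test_same_seed_identical_posterior(self):
        data = _dataset()
        a = run_mcmc(data, n_chains=2, n_steps=500, seed=3)
        b = run_mcmc(data, n_chains=2, n_steps=500, seed=3)
        assert a.samples.equals(b.samples)
        assert a.acceptance_rate == b.acceptance_rate

    def test_parameter_recovery_low_noise(self):
        data = _dataset(K_M=100.0, k_cat=10.0, noise=0.01, seed=1)
        prior = PriorSpec(noise_scale=float(np.mean(data.v_obs)))
        post = run_mcmc(data, prior, n_chains=2, n_steps=6000, seed=2)
        assert post.median("K_M") == pytest.approx(100.0, rel=0.10)
        assert post.median("k_cat") == pytest.approx(10.0, rel=0.10)
        assert 0.15 < post.acceptance_rate < 0.55

    def test_prior_recovery_without_likelihood(self):
        # flat likelihood: sampled quantiles must match the prior's within
        # Monte-Carlo error, estimated from the between-chain spread (a
        # systematic bias would shift every chain identically and fail)
        prior = PriorSpec()
        post = run_mcmc(None, prior, n_chains=8, n_steps=5000, seed=11)
        assert len(post.samples) >= 10_000
        m = len(post.samples) // post.n_chains
        for name, pp in (("K_M", prior.K_M), ("k_cat", prior.k_cat)):
            x = np.log(post.samples[name].to_numpy())
            for q in (0.25, 0.5, 0.75):
                per_chain = [
                    np.quantile(x[i * m : (i + 1) * m], q) for i in range(post.n_chains)
                ]
                se = np.std(per_chain, ddof=1) / np.sqrt(post.n_chains)
                dev = np.quantile(x, q) - np.log(pp.quantile(q))
                assert abs(dev) <= max(6 * se, 0.05)

    def test_posterior_within_prior_support(self):
        prior = PriorSpec()
        post = run_mcmc(_dataset(), prior, n_chains=2, n_steps=1000, seed=4)
        assert post.samples["K_M"].between(prior.K_M.low, prior.K_M.high).all()
        assert post.samples["k_cat"].between(prior.k_cat.low, prior.k_cat.high).all()

    def test_contraction_with_more_design_points(self):
        rng = np.random.default_rng(0)
        S14 = np.sort(np.concatenate([S7, S7 * 1.5]))
        sds = {}
        for S in (S7, S14):
            v = mm_rate(S, 10.0 * E_TOTAL, 100.0)
            v_obs = np.maximum(v * (1 + 0.05 * rng.standard_normal(len(S))), 0)
            data = RateDataset(S=S, v_obs=v_obs, E_total=E_TOTAL)
            prior = PriorSpec(noise_scale=float(np.mean(v_obs)))
            post = run_mcmc(data, prior, n_chains=2, n_steps=6000, seed=9)
            sds[len(S)] = np.std(np.log(post.samples["K_M"]))
        assert sds[14] < sds[7]

    def test_unit_rescaling_leaves_kcat_posterior_invariant(self):
        data = _dataset(noise=0.02, seed=6)
        # μM -> nM: concentrations and rates scale by 1000; K_M prior follows
        data_nM = RateDataset(S=data.S * 1e3, v_obs=data.v_obs * 1e3, E_total=data.E_total * 1e3)
        prior_uM = PriorSpec(noise_scale=float(np.mean(data.v_obs)))
        prior_nM = PriorSpec(
            K_M=ParameterPrior("log-uniform", low=1e3, high=1e7),
            noise_scale=float(np.mean(data_nM.v_obs)),
        )
        post_uM = run_mcmc(data, prior_uM, n_chains=2, n_steps=6000, seed=8)
        post_nM = run_mcmc(data_nM, prior_nM, n_chains=2, n_steps=6000, seed=8)
        assert post_nM.median("k_cat") == pytest.approx(post_uM.median("k_cat"), rel=0.05)
        assert post_nM.median("K_M") == pytest.approx(1e3 * post_uM.median("K_M"), rel=0.05)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            run_mcmc(_dataset(), n_chains=1, n_steps=100, seed=0)


class TestEmceeCrossCheck:
    def test_medians_agree_with_ensemble_sampler(self):
        # independent sampler on the identical log-posterior
        emcee = pytest.importorskip("emcee")
        data = _dataset(noise=0.03, seed=12)
        prior = PriorSpec(noise_scale=float(np.mean(data.v_obs)))

        def log_prob(log_theta):
            return log_posterior(np.exp(log_theta), data, prior)

        rng = np.random.default_rng(1)
        nwalkers, ndim = 16, 3
        p0 = np.column_stack(
            [
                rng.uniform(np.log(50), np.log(200), nwalkers),
                rng.uniform(np.log(5), np.log(20), nwalkers),
                rng.uniform(np.log(0.001), np.log(0.1), nwalkers),
            ]
        )
        sampler = emcee.EnsembleSampler(nwalkers, ndim, log_prob)
        sampler.run_mcmc(p0, 2000, progress=False)
        flat = np.exp(sampler.get_chain(discard=1000, flat=True))

        post = run_mcmc(data, prior, n_chains=2, n_steps=8000, seed=13)
        assert post.median("K_M") == pytest.approx(np.median(flat[:, 0]), rel=0.10)
        assert post.median("k_cat") == pytest.approx(np.median(flat[:, 1]), rel=0.05)


class TestSummaries:
    def _degenerate_posterior(self, value=5.0, n=100):
        import pandas as pd

        samples = pd.DataFrame(
            {"K_M": np.full(n, value), "k_cat": np.full(n, value), "noise_sd": np.full(n, value)}
        )
        return Posterior(
            samples=samples,
            acceptance_rate=0.3,
            n_chains=2,
            burn_in=10,
            rhat={"K_M": 1.0, "k_cat": 1.0, "noise_sd": 1.0},
            converged=True,
            seed=0,
        )

    def test_degenerate_samples(self):
        summary = summarize_posterior(self._degenerate_posterior(5.0)).set_index("parameter")
        assert summary.loc["K_M", "median"] == 5.0
        assert summary.loc["K_M", "mean"] == 5.0
        assert summary.loc["K_M", "sd"] == 0.0

    def test_quantiles_match_sort_oracle(self):
        post = run_mcmc(_dataset(), n_chains=2, n_steps=1000, seed=5)
        summary = summarize_posterior(post).set_index("parameter")
        x = np.sort(post.samples["K_M"].to_numpy())
        assert summary.loc["K_M", "q05"] == pytest.approx(np.quantile(x, 0.05))
        assert summary.loc["K_M", "q95"] == pytest.approx(np.quantile(x, 0.95))
        assert summary.loc["K_M", "median"] == pytest.approx(x[len(x) // 2], rel=0.01)

    def test_empty_posterior_rejected(self):
        import pandas as pd

        post = Posterior(
            samples=pd.DataFrame(columns=["K_M", "k_cat", "noise_sd"]),
            acceptance_rate=0.0,
            n_chains=2,
            burn_in=0,
            rhat={},
            converged=False,
            seed=0,
        )
        with pytest.raises(ValueError):
            summarize_posterior(post)


class TestSplitRhat:
    def test_identical_chains_give_one(self):
        rng = np.random.default_rng(0)
        chain = rng.standard_normal(1000)
        assert split_rhat(np.stack([chain, chain])) == pytest.approx(1.0, abs=0.01)

    def test_disjoint_chains_give_large_value(self):
        rng = np.random.default_rng(0)
        a = rng.standard_normal(1000)
        assert split_rhat(np.stack([a, a + 50.0])) > 2.0

    def test_matches_arviz(self):
        az = pytest.importorskip("arviz")
        rng = np.random.default_rng(3)
        chains = rng.standard_normal((4, 500)) + rng.standard_normal((4, 1))
        ours = split_rhat(chains)
        theirs = float(az.rhat(az.convert_to_dataset(chains[:, :, None]))["x"].values[0])
        assert ours == pytest.approx(theirs, rel=0.02)
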