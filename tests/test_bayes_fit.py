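"""Metropolis-Hastings and Gibbs updates, the full sampler, and DIC."""

import numpy as np
import pytest

from nestnet.bayes_fit import (
    IndividualData,
    McmcConfig,
    ModelSpec,
    NonIdentifiableError,
    PosteriorChain,
    adapt_proposal,
    compute_dic,
    enumerate_model_family,
    gibbs_update_alpha,
    gibbs_update_sigma,
    make_loglik,
    mh_update_beta,
    potential_scale_reduction,
    run_chains,
    run_mcmc,
)


def batch_mcse(x, n_batches=50):
    """Batch-means Monte-Carlo standard error for a correlated chain."""
    x = np.asarray(x)
    k = len(x) // n_batches
    means = x[: k * n_batches].reshape(n_batches, k).mean(axis=1)
    return means.std(ddof=1) / np.sqrt(n_batches)


class TestMhUpdateBeta:
    def test_tiny_proposal_accepts_almost_always(self, rng):
        mu, Sigma_inv = np.zeros(3), np.eye(3)
        beta = np.array([0.5, -0.2, 0.1])
        accepted = 0
        ll = None
        for _ in range(500):
            beta, acc, ll = mh_update_beta(
                beta, lambda b: 0.0, mu, Sigma_inv, 1e-8, rng, ll
            )
            accepted += acc
        assert accepted / 500 > 0.99

    def test_flat_likelihood_recovers_prior(self, rng):
        # with no transitions the posterior of beta_l is exactly N(mu, Sigma)
        mu = np.array([1.0, -0.5, 0.3])
        Sigma = np.diag([0.4, 0.1, 0.2])
        Sigma_inv = np.linalg.inv(Sigma)
        beta, ll = mu.copy(), None
        draws = np.empty((20_000, 3))
        for t in range(len(draws)):
            beta, _, ll = mh_update_beta(
                beta, lambda b: 0.0, mu, Sigma_inv, 0.8, rng, ll
            )
            draws[t] = beta
        for k in range(3):
            mcse = batch_mcse(draws[:, k])
            assert abs(draws[:, k].mean() - mu[k]) <= 3 * mcse
            var_mcse = batch_mcse((draws[:, k] - mu[k]) ** 2)
            assert abs(draws[:, k].var() - Sigma[k, k]) <= 3 * var_mcse + 1e-3

    def test_empirical_reversibility_on_binned_states(self, rng):
        # stationary MH flow between state bins must be symmetric
        mu, Sigma_inv = np.zeros(1), np.eye(1)
        edges = np.array([-np.inf, -1.0, -0.3, 0.3, 1.0, np.inf])
        beta, ll = np.zeros(1), None
        states = np.empty(100_000)
        for t in range(len(states)):
            beta, _, ll = mh_update_beta(beta, lambda b: 0.0, mu, Sigma_inv, 1.0, rng, ll)
            states[t] = beta[0]
        bins = np.digitize(states, edges[1:-1])
        flow = np.zeros((5, 5))
        for a, b in zip(bins, bins[1:]):
            flow[a, b] += 1
        for a in range(5):
            for b in range(a + 1, 5):
                tot = flow[a, b] + flow[b, a]
                if tot > 0:
                    assert abs(flow[a, b] - flow[b, a]) <= 4 * np.sqrt(tot)

    def test_nonfinite_proposal_rejected(self, rng):
        beta = np.zeros(2)

        def loglik(b):
            return -np.inf if b[0] > 0 else 0.0

        for _ in range(50):
            new, acc, _ = mh_update_beta(beta, loglik, np.zeros(2), np.eye(2), 5.0, rng)
            assert new[0] <= 0


class TestGibbsAlpha:
    def test_identical_betas_balanced_sexes(self, rng):
        b = np.array([1.5, -0.7, 0.2])
        betas = np.tile(b, (6, 1))
        sexes = np.array([-1, -1, -1, 1, 1, 1])
        draws = np.array([
            np.concatenate(gibbs_update_alpha(betas, sexes, np.eye(3), rng))
            for _ in range(5000)
        ])
        se = draws.std(axis=0, ddof=1) / np.sqrt(len(draws))
        expected = np.concatenate([b, np.zeros(3)])
        assert np.all(np.abs(draws.mean(axis=0) - expected) <= 4 * se)

    def test_two_individual_orthogonal_design(self, rng):
        b_plus, b_minus = np.array([2.0, 0.5, -1.0]), np.array([1.0, -0.5, 0.0])
        betas = np.vstack([b_minus, b_plus])
        sexes = np.array([-1, 1])
        draws = np.array([
            np.concatenate(gibbs_update_alpha(betas, sexes, np.eye(3), rng))
            for _ in range(5000)
        ])
        expected = np.concatenate([(b_plus + b_minus) / 2, (b_plus - b_minus) / 2])
        se = draws.std(axis=0, ddof=1) / np.sqrt(len(draws))
        assert np.all(np.abs(draws.mean(axis=0) - expected) <= 4 * se)

    def test_single_sex_raises(self, rng):
        betas = np.zeros((3, 2))
        with pytest.raises(NonIdentifiableError):
            gibbs_update_alpha(betas, np.ones(3), np.eye(2), rng)
        a0, a1 = gibbs_update_alpha(betas, np.ones(3), np.eye(2), rng, fix_alpha1=True)
        assert np.all(a1 == 0)


class TestGibbsSigma:
    def test_zero_residuals_closed_form_mean(self, rng):
        # residuals 0, n individuals: posterior IW(I, 4 + n), mean I / n (p=3)
        n = 8
        betas = np.tile(np.array([1.0, 2.0, 3.0]), (n, 1))
        sexes = np.array([-1, 1] * 4)
        a0, a1 = np.array([1.0, 2.0, 3.0]), np.zeros(3)
        draws = np.array([
            gibbs_update_sigma(betas, a0, a1, sexes, rng) for _ in range(4000)
        ])
        mean = draws.mean(axis=0)
        se = draws.std(axis=0, ddof=1) / np.sqrt(len(draws))
        assert np.all(np.abs(mean - np.eye(3) / n) <= 4 * se + 1e-3)

    def test_no_individuals_draws_prior(self, rng):
        draws = np.array([
            gibbs_update_sigma(np.zeros((0, 3)), np.zeros(3), np.zeros(3),
                               np.zeros(0), rng)
            for _ in range(200)
        ])
        # IW(I, 4) with p=3 has no finite mean (nu - p - 1 = 0); check PD draws
        for S in draws[:20]:
            np.linalg.cholesky(S)

    def test_moments_match_iw_formula(self, rng):
        n, p = 10, 3
        r = rng.normal(0, 1.0, (n, p))
        betas = r  # mu = 0
        sexes = np.array([-1, 1] * 5)
        S = r.T @ r
        expected = (np.eye(p) + S) / (4 + n - p - 1)
        draws = np.array([
            gibbs_update_sigma(betas, np.zeros(p), np.zeros(p), sexes, rng)
            for _ in range(5000)
        ])
        se = draws.std(axis=0, ddof=1) / np.sqrt(len(draws))
        assert np.all(np.abs(draws.mean(axis=0) - expected) <= 4 * se)


class TestAdaptProposal:
    def test_on_target_unchanged(self):
        assert adapt_proposal(0.23, 1.7) == pytest.approx(1.7)

    def test_over_acceptance_grows_scale(self):
        s = 0.5
        for _ in range(5):
            s_new = adapt_proposal(1.0, s)
            assert s_new > s
            s = s_new

    def test_under_acceptance_shrinks_scale(self):
        assert adapt_proposal(0.0, 1.0) < 1.0


class TestRunMcmc:
    def test_chain_length_and_determinism(self, small_dataset):
        data = list(small_dataset.data)
        spec = ModelSpec(use_distance=True)
        cfg = McmcConfig(iterations=201, burn_in=200, seed=5)
        chain = run_mcmc(data, spec, cfg)
        assert chain.n_draws == 1
        cfg2 = McmcConfig(iterations=400, burn_in=100, seed=9)
        c1 = run_mcmc(data, spec, cfg2)
        c2 = run_mcmc(data, spec, cfg2)
        assert np.array_equal(c1.betas, c2.betas)
        assert np.array_equal(c1.Sigma, c2.Sigma)

    def test_inactive_components_stay_zero(self, small_dataset):
        data = list(small_dataset.data)
        chain = run_mcmc(data, ModelSpec(use_distance=True),
                         McmcConfig(iterations=300, burn_in=100, seed=3))
        assert np.all(chain.betas[:, :, 2] == 0.0)
        assert np.all(chain.alpha0[:, 2] == 0.0)

    def test_single_sex_dataset_needs_flag(self, small_dataset):
        females = [d for d in small_dataset.data if d.sex == -1]
        spec = ModelSpec(use_distance=True)
        with pytest.raises(NonIdentifiableError):
            run_mcmc(females, spec, McmcConfig(iterations=120, burn_in=20, seed=1))
        chain = run_mcmc(
            females, spec,
            McmcConfig(iterations=120, burn_in=20, seed=1, fix_alpha1_single_sex=True),
        )
        assert np.all(chain.alpha1 == 0.0)

    def test_dispersed_chains_mix(self, study_dataset):
        # needs data at the study's scale: a handful of individuals leaves
        # the hierarchy heavy-tailed and slow to traverse
        data = list(study_dataset.data)
        spec = ModelSpec(use_distance=True)
        cfg = McmcConfig(iterations=4000, burn_in=1500, seed=7)
        chains = run_chains(data, spec, cfg, n_chains=3)
        for k in (0, 1):
            for vec in ("alpha0", "alpha1"):
                psrf = potential_scale_reduction(
                    [getattr(c, vec)[:, k] for c in chains]
                )
                assert psrf < 1.1, (vec, k)

    def test_more_individuals_tighter_alpha0(self):
        from nestnet.synthetic_data import SimulationScenario, generate_dataset

        widths = {}
        for n in (4, 16):
            sc = SimulationScenario(seed=31, n_females=n // 2, n_males=n // 2,
                                    observation_days=60)
            ds = generate_dataset(sc)
            chain = run_mcmc(
                list(ds.data), ModelSpec(use_distance=True),
                McmcConfig(iterations=1500, burn_in=500, seed=13),
            )
            lo, hi = np.percentile(chain.alpha0[:, 0], [2.5, 97.5])
            widths[n] = hi - lo
        assert widths[16] < widths[4]


class TestModelFamily:
    def test_family_has_25_models(self):
        family = enumerate_model_family()
        assert len(family) == 25
        names = {m.name for m in family}
        assert len(names) == 25
        assert sum(m.use_distance and not m.use_connectivity for m in family) == 1
        assert sum(m.use_connectivity and not m.use_distance for m in family) == 12
        assert sum(m.use_distance and m.use_connectivity for m in family) == 12

    def test_spec_validation(self):
        with pytest.raises(Exception):
            ModelSpec(use_distance=False, use_connectivity=False)
        with pytest.raises(Exception):
            ModelSpec(use_distance=False, use_connectivity=True)


def degenerate_chain(data, spec, betas_fixed, n_draws=150):
    """A chain whose every draw is identical (for DIC closed-form checks)."""
    n_ind = len(data)
    dev = -2.0 * sum(
        make_loglik(ind, spec)(betas_fixed[l]) for l, ind in enumerate(data)
    )
    return PosteriorChain(
        spec=spec, config=McmcConfig(iterations=n_draws + 1, burn_in=1, seed=0),
        active=spec.active,
        alpha0=np.zeros((n_draws, 3)), alpha1=np.zeros((n_draws, 3)),
        Sigma=np.tile(np.eye(len(spec.active)), (n_draws, 1, 1)),
        betas=np.tile(betas_fixed, (n_draws, 1, 1)),
        deviance=np.full(n_draws, dev),
        acceptance=np.zeros(n_ind), proposal_scales=np.ones(n_ind),
    )


class TestDic:
    def test_degenerate_chain_pd_zero(self, small_dataset):
        data = list(small_dataset.data)
        spec = ModelSpec(use_distance=True)
        betas = np.tile(np.array([1.0, -0.4, 0.0]), (len(data), 1))
        chain = degenerate_chain(data, spec, betas)
        dic, d_bar, p_d = compute_dic(chain, data)
        assert p_d == pytest.approx(0.0, abs=1e-9)
        assert dic == pytest.approx(d_bar)

    def test_duplicating_data_doubles_deviance(self, small_dataset):
        data = list(small_dataset.data)
        spec = ModelSpec(use_distance=True)
        betas = np.tile(np.array([0.8, -0.3, 0.0]), (len(data), 1))
        dic1, _, _ = compute_dic(degenerate_chain(data, spec, betas), data)
        data2 = data + data
        betas2 = np.vstack([betas, betas])
        dic2, _, _ = compute_dic(degenerate_chain(data2, spec, betas2), data2)
        assert dic2 == pytest.approx(2 * dic1)

    def test_needs_enough_draws(self, small_dataset):
        data = list(small_dataset.data)
        spec = ModelSpec(use_distance=True)
        betas = np.zeros((len(data), 3))
        with pytest.raises(ValueError):
            compute_dic(degenerate_chain(data, spec, betas, n_draws=50), data)


class TestPsrf:
    def test_identical_distribution_near_one(self, rng):
        chains = [rng.normal(0, 1, 2000) for _ in range(3)]
        assert potential_scale_reduction(chains) < 1.05

    def test_shifted_chain_flags(self, rng):
        chains = [rng.normal(0, 1, 2000), rng.normal(4, 1, 2000)]
        assert potential_scale_reduction(chains) > 1.5
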