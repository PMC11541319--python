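"""Sampler building blocks: Metropolis updates, antithetic streams,
slice sampling under the mean-one constraint, diagnostics, and a
scaled-down parameter-recovery run."""

import math

import numpy as np
import pytest

import valueshift as vs
from valueshift.model import CompiledData, ModelParams, PriorSpec, lognormal_logpdf
from valueshift.mcmc import (
    AntitheticRNG,
    MCMCConfig,
    PosteriorDraws,
    fit,
    gelman_rubin,
    initialize_params,
    mh_update_scalar,
    run_chain,
    slice_update_phi,
)


class TestMHUpdateScalar:
    def test_flat_target_always_accepts(self):
        rng = np.random.default_rng(0)
        flat = lambda x: 0.0
        acc = sum(
            mh_update_scalar(0.0, flat, 1.0, rng)[1] for _ in range(10_000)
        )
        assert acc == 10_000

    def test_standard_normal_target_moments(self):
        rng = np.random.default_rng(1)
        logp = lambda x: -0.5 * x * x
        x, draws = 0.0, np.empty(50_000)
        for i in range(50_000):
            x, _ = mh_update_scalar(x, logp, 2.4, rng)
            draws[i] = x
        # random-walk chains autocorrelate; allow ~3 SE at a conservative ESS
        assert abs(draws.mean()) < 0.05
        assert abs(draws.var() - 1.0) < 0.08

    def test_nonfinite_current_state_rejected(self):
        rng = np.random.default_rng(2)
        with pytest.raises(ValueError, match="finite"):
            mh_update_scalar(0.0, lambda x: -math.inf, 1.0, rng)


def test_antithetic_innovations_mirror_exactly():
    # a generator and its mirror produce innovation pairs (z, -z) that
    # sum to zero exactly, and reflected acceptance uniforms
    plain = np.random.default_rng(3)
    mirror = AntitheticRNG(3)
    sums = [plain.standard_normal() + mirror.standard_normal() for _ in range(100)]
    assert sums == [0.0] * 100
    plain2 = np.random.default_rng(3)
    assert all(plain2.uniform() + AntitheticRNG(3).uniform() == 1.0 for _ in range(1))


def test_antithetic_chain_pairs_anticorrelated_and_valid():
    # the mirrored chain has the same marginal law; paired chains are
    # negatively correlated so their pooled average is more precise
    import math
    def chain(rng, n=20_000, step=8.0, sd=10.0):
        x, out = 0.0, np.empty(n)
        for i in range(n):
            prop = x + step * float(rng.standard_normal())
            if math.log(rng.uniform()) < -0.5 * (prop**2 - x**2) / sd**2:
                x = prop
            out[i] = x
        return out
    a = chain(np.random.default_rng(11))
    b = chain(AntitheticRNG(11))
    assert abs(b.std() - 10.0) < 1.0  # mirrored chain still targets N(0, 10)
    assert np.corrcoef(a, b)[0, 1] < -0.5


class TestSliceUpdatePhi:
    def test_lognormal_pseudo_target_mean_one(self):
        # prior with log-mean -sigma^2/2 has expectation exactly 1
        rng = np.random.default_rng(4)
        logp = lambda x: lognormal_logpdf(float(x[0]), -0.08, 0.4)
        x = np.array([1.0])
        draws = np.empty(50_000)
        for i in range(50_000):
            x = slice_update_phi(x, logp, 0.4, rng, total=100.0)
            draws[i] = x[0]
        se = draws.std() / math.sqrt(2000)  # conservative ESS
        assert abs(draws.mean() - 1.0) < 3 * se + 0.01

    def test_derived_cell_never_nonpositive(self):
        rng = np.random.default_rng(5)
        flat = lambda x: 0.0
        x = np.array([1.0])  # G = 2, derived = 2 - x
        for _ in range(2000):
            x = slice_update_phi(x, flat, 0.5, rng, total=2.0)
            assert 0.0 < x[0] < 2.0

    def test_uniform_target_empirical_cdf(self):
        # flat target truncated to (0, 2): draws should be U(0, 2)
        rng = np.random.default_rng(6)
        flat = lambda x: 0.0
        x = np.array([1.0])
        draws = np.empty(20_000)
        for i in range(20_000):
            x = slice_update_phi(x, flat, 0.7, rng, total=2.0)
            draws[i] = x[0]
        grid = np.linspace(0.05, 1.95, 20)
        ecdf = np.searchsorted(np.sort(draws), grid) / len(draws)
        assert np.max(np.abs(ecdf - grid / 2.0)) < 0.03


class TestGelmanRubin:
    def test_iid_same_distribution_rhat_near_one(self):
        rng = np.random.default_rng(7)
        chains = rng.standard_normal((2, 5000))
        assert gelman_rubin(chains) < 1.01

    def test_separated_chains_rhat_large(self):
        rng = np.random.default_rng(8)
        chains = np.stack([rng.normal(0, 1, 1000), rng.normal(10, 1, 1000)])
        assert gelman_rubin(chains) > 3.0

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError, match="2 chains"):
            gelman_rubin(np.zeros((1, 100)))

    def test_zero_variance_undefined(self):
        assert math.isnan(gelman_rubin(np.ones((2, 100))))

    def test_agrees_with_arviz_split_rhat(self):
        az = pytest.importorskip("arviz")
        rng = np.random.default_rng(9)
        chains = rng.standard_normal((3, 400)).cumsum(axis=1) * 0.05 + \
            rng.standard_normal((3, 400))
        ours = gelman_rubin(chains)
        theirs = float(
            az.rhat(az.convert_to_dataset(chains[:, :, None]))["x"].values.ravel()[0]
        )
        assert ours == pytest.approx(theirs, abs=0.05)


class TestInitializeParams:
    def test_valid_params_and_overdispersion(self, small_dataset):
        inits = [
            initialize_params(small_dataset, np.random.default_rng(s))
            for s in (0, 1, 2)
        ]
        for p in inits:
            assert np.all(p.phi > 0)
            np.testing.assert_allclose(p.phi.mean(axis=1), 1.0, atol=1e-10)
        assert len({p.beta0 for p in inits}) == 3

    def test_near_noiseless_data_recovers_beta(self):
        truth = vs.default_truth("UK", n_respondents=200, contaminate=False)
        truth.params.gamma = np.array([-6.0, 0, 0, 0, 0])  # sigma ~ 0.0025
        truth.params.phi = np.ones((5, 8))
        ds = vs.simulate_study(truth, rng=np.random.default_rng(10))
        p = initialize_params(ds, np.random.default_rng(11))
        assert abs(p.beta0 - truth.params.beta0) < 0.05
        np.testing.assert_allclose(p.beta, truth.params.beta, atol=0.05)

    def test_all_censored_rejected(self):
        cells = vs.standard_cells()
        data = CompiledData.empty(cells)
        with pytest.raises(ValueError, match="uncensored"):
            initialize_params(data, np.random.default_rng(0))


class TestRunChain:
    def test_retained_draw_bookkeeping(self, small_compiled):
        cfg = MCMCConfig(n_chains=1, n_burnin=50, n_total=150, seed=1)
        d = run_chain(small_compiled, cfg, chain_seed=1)
        assert d.n_draws == 100 and d.n_chains == 1

    def test_same_seed_bit_identical(self, small_compiled):
        cfg = MCMCConfig(n_chains=2, n_burnin=50, n_total=120, seed=9)
        a, b = fit(small_compiled, cfg), fit(small_compiled, cfg)
        assert np.array_equal(a.beta0, b.beta0)
        assert np.array_equal(a.beta, b.beta)
        assert np.array_equal(a.phi, b.phi)

    def test_all_draws_satisfy_constraints(self, small_compiled):
        cfg = MCMCConfig(n_chains=1, n_burnin=100, n_total=300, seed=3)
        d = run_chain(small_compiled, cfg, chain_seed=3)
        assert np.all(d.phi > 0)
        np.testing.assert_allclose(d.phi.mean(axis=3), 1.0, atol=1e-10)

    def test_scaled_down_parameter_recovery(self):
        # betas recovered within 3 posterior SDs from a small study
        truth = vs.default_truth("UK", n_respondents=300, contaminate=False)
        ds = vs.simulate_study(truth, rng=np.random.default_rng(21))
        cfg = MCMCConfig(n_chains=1, n_burnin=400, n_total=1400, seed=22)
        d = fit(CompiledData.from_dataset(ds), cfg)
        flat_beta = d.beta.reshape(-1, 10)
        for j in range(10):
            post_mean = flat_beta[:, j].mean()
            post_sd = flat_beta[:, j].std()
            assert abs(post_mean - truth.params.beta[j]) < 3.5 * post_sd

    def test_flat_table_round_trip(self, small_compiled):
        cfg = MCMCConfig(n_chains=2, n_burnin=20, n_total=40, seed=5)
        d = fit(small_compiled, cfg)
        back = PosteriorDraws.from_flat_table(d.to_flat_table(), d.cells)
        np.testing.assert_array_equal(d.beta0, back.beta0)
        np.testing.assert_array_equal(d.phi, back.phi)


class TestPriorRecovery:
    """With no data the sampler must reproduce the priors."""

    def test_beta_marginal_and_phi_mean_one(self):
        cells = vs.standard_cells()
        data = CompiledData.empty(cells)
        init = ModelParams(0.0, np.zeros(10), np.zeros(5), np.ones((5, 8)), cells)
        cfg = MCMCConfig(
            n_chains=1, n_burnin=500, n_total=13_000, seed=17,
            step_beta0=8.0, step_beta=8.0, step_gamma=8.0, slice_w=0.5,
        )
        d = run_chain(data, cfg, init=init, priors=PriorSpec())
        b = d.beta0.reshape(-1)
        # Normal(0, 10) marginal: generous bounds for autocorrelated draws
        assert abs(b.mean()) < 1.5
        assert abs(b.std() - 10.0) < 1.5
        np.testing.assert_allclose(d.phi.mean(axis=3), 1.0, atol=1e-10)
        assert np.all(d.phi > 0)
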