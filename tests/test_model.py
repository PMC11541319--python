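"""Tobit likelihood, mean/variance structure and priors, checked
against independent scalar oracles."""

import math

import numpy as np
import pytest
from scipy import integrate, stats

import valueshift as vs
from valueshift.core import DemographicCell, HealthState, encode_state, standard_cells
from valueshift.model import (
    CompiledData,
    ModelParams,
    PriorSpec,
    linear_predictor,
    log_prior,
    loglik_arrays,
    scale_sd,
    tobit_loglik_obs,
    total_loglik,
)

CELLS = standard_cells()


def _params(beta0=1.0, beta=None, gamma=None, phi=None):
    beta = np.zeros(10) if beta is None else np.asarray(beta, float)
    gamma = np.zeros(5) if gamma is None else np.asarray(gamma, float)
    phi = np.ones((5, 8)) if phi is None else np.asarray(phi, float)
    return ModelParams(beta0, beta, gamma, phi, CELLS)


def _random_valid_params(rng):
    beta = -rng.uniform(0.02, 0.5, 10)
    gamma = np.array([rng.uniform(-1.5, -0.5), rng.uniform(-0.6, 0.2),
                      rng.uniform(-0.1, 0.1), 0.0, 0.0])
    dev = rng.uniform(-0.2, 0.2, (5, 8))
    phi = 1.0 + dev - dev.mean(axis=1, keepdims=True)
    return ModelParams(rng.uniform(0.8, 1.0), beta, gamma, phi, CELLS)


class TestModelParams:
    def test_constraint_enforced(self):
        phi = np.ones((5, 8))
        phi[2, 0] = 1.5  # breaks the mean-one constraint
        with pytest.raises(ValueError, match="mean-of-one"):
            ModelParams(1.0, np.zeros(10), np.zeros(5), phi, CELLS)

    def test_positivity_enforced(self):
        phi = np.ones((5, 8))
        phi[0, 0], phi[0, 1] = -0.5, 2.5  # mean still 1
        with pytest.raises(ValueError, match="positive"):
            ModelParams(1.0, np.zeros(10), np.zeros(5), phi, CELLS)


class TestLinearPredictor:
    def test_full_health_returns_intercept(self):
        p = _random_valid_params(np.random.default_rng(0))
        mu = linear_predictor(p, encode_state("11111"), CELLS[3])
        assert mu == pytest.approx(p.beta0)

    def test_hand_arithmetic_single_decrement(self):
        beta = np.zeros(10)
        beta[1] = -0.4  # MO3
        phi = np.ones((5, 8))
        phi[0] = [1.25, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 0.75]
        p = _params(beta0=1.0, beta=beta, phi=phi)
        mu = linear_predictor(p, encode_state("31111"), CELLS[0])
        assert mu == pytest.approx(1.0 + (-0.4) * 1.25)  # = 0.5

    def test_unit_phi_reduces_to_main_effects_for_all_states(self):
        rng = np.random.default_rng(1)
        beta = -rng.uniform(0.05, 0.5, 10)
        p = _params(beta0=0.9, beta=beta)
        for state in vs.core.all_states():
            x = encode_state(state)
            expected = 0.9 + float(beta @ x)
            for cell in CELLS:
                assert linear_predictor(p, x, cell) == pytest.approx(expected)

    def test_unknown_cell_rejected(self):
        p = _params()
        short_cells = CELLS[:4]
        p2 = ModelParams(1.0, np.zeros(10), np.zeros(5), np.ones((5, 4)), short_cells)
        with pytest.raises(ValueError, match="75"):
            linear_predictor(p2, encode_state("11111"), DemographicCell("female", "75+"))


class TestScaleSD:
    def test_constant_variance_limit(self):
        p = _params(gamma=[math.log(0.3), 0, 0, 0, 0])
        for mu in (-1.0, 0.0, 0.7):
            assert scale_sd(p, mu) == pytest.approx(0.3)

    def test_exp_zero(self):
        p = _params(gamma=[0, 1, 0, 0, 0])
        assert scale_sd(p, 0.0) == pytest.approx(1.0)

    def test_horner_oracle(self):
        p = _params(gamma=[0.1, -0.2, 0.05, 0, 0])
        mu = 0.5
        expected = math.exp(0.1 - 0.2 * 0.5 + 0.05 * 0.25)
        assert scale_sd(p, mu) == pytest.approx(expected, rel=1e-14)

    def test_overflow_rejected(self):
        p = _params(gamma=[1000.0, 0, 0, 0, 0])
        with pytest.raises(ValueError, match="divergent"):
            scale_sd(p, 0.0)


class TestTobitLoglikObs:
    def test_censored_mass_is_normal_cdf(self):
        expected = stats.norm.logcdf((-1 - 0.0) / 1.0)
        assert tobit_loglik_obs(-1.0, 0.0, 1.0) == pytest.approx(expected, abs=1e-12)
        assert tobit_loglik_obs(-1.0, 0.0, 1.0) == pytest.approx(-1.841021645, abs=1e-8)

    def test_interior_is_normal_density(self):
        got = tobit_loglik_obs(0.5, 0.0, 1.0)
        assert got == pytest.approx(stats.norm.logpdf(0.5), abs=1e-12)
        assert got == pytest.approx(-0.91894 - 0.125, abs=1e-5)

    def test_zero_residual_any_scale(self):
        for s in (0.1, 1.0, 3.0):
            assert tobit_loglik_obs(0.5, 0.5, s) == pytest.approx(
                -math.log(s) - 0.5 * math.log(2 * math.pi)
            )

    def test_below_censor_rejected(self):
        with pytest.raises(ValueError, match="below"):
            tobit_loglik_obs(-1.5, 0.0, 1.0)

    def test_censored_mass_conservation(self):
        # P(censored) + integral of density above the censor point = 1
        rng = np.random.default_rng(3)
        for _ in range(10):
            mu, sigma = rng.uniform(-2, 1), rng.uniform(0.1, 1.0)
            p_cens = math.exp(tobit_loglik_obs(-1.0, mu, sigma))
            dens, _ = integrate.quad(
                lambda v: stats.norm.pdf(v, mu, sigma), -1.0, np.inf
            )
            assert p_cens + dens == pytest.approx(1.0, abs=1e-6)

    def test_uncensored_loglik_maximized_at_value(self):
        p = _params(gamma=[math.log(0.3), 0, 0, 0, 0])
        value = 0.4
        grid = np.linspace(-0.5, 1.2, 341)
        lls = [tobit_loglik_obs(value, m, 0.3) for m in grid]
        assert abs(grid[int(np.argmax(lls))] - value) < 0.01


def scalar_total_loglik(params, dataset):
    """Independent one-pass scalar oracle for the full likelihood."""
    total = 0.0
    for r, obs in dataset.iter_observations():
        mu = linear_predictor(params, encode_state(obs.state), r.cell)
        sigma = scale_sd(params, mu)
        total += tobit_loglik_obs(obs.value, mu, sigma)
    return total


class TestTotalLoglik:
    def test_empty_dataset_is_zero(self):
        p = _params()
        assert total_loglik(p, CompiledData.empty(CELLS)) == 0.0

    def test_single_observation(self):
        ds = vs.io.ValuationDataset(
            [vs.RespondentRecord(
                "r1", CELLS[0],
                [vs.TTOObservation("r1", HealthState("21111"), 0.3)],
            )]
        )
        p = _random_valid_params(np.random.default_rng(5))
        mu = linear_predictor(p, encode_state("21111"), CELLS[0])
        assert total_loglik(p, ds) == pytest.approx(
            tobit_loglik_obs(0.3, mu, scale_sd(p, mu)), abs=1e-12
        )

    def test_matches_scalar_oracle_on_random_datasets(self):
        rng = np.random.default_rng(11)
        for trial in range(100):
            truth = vs.default_truth("UK", n_respondents=4, contaminate=False)
            ds = vs.simulate_study(truth, rng=rng)
            p = _random_valid_params(rng)
            fast = total_loglik(p, ds)
            slow = scalar_total_loglik(p, ds)
            assert fast == pytest.approx(slow, abs=1e-10)

    def test_homoskedastic_limit_matches_plain_tobit(self):
        # phi = 1 and gamma_1..4 = 0 reduce to an ordinary Tobit model
        rng = np.random.default_rng(13)
        truth = vs.default_truth("UK", n_respondents=30, contaminate=False)
        ds = vs.simulate_study(truth, rng=rng)
        sigma = 0.35
        beta0, beta = 0.9, -rng.uniform(0.05, 0.4, 10)
        p = _params(beta0=beta0, beta=beta, gamma=[math.log(sigma), 0, 0, 0, 0])
        plain = 0.0
        for r, obs in ds.iter_observations():
            mu = beta0 + float(beta @ encode_state(obs.state))
            if obs.censored:
                plain += stats.norm.logcdf(-1.0, mu, sigma)
            else:
                plain += stats.norm.logpdf(obs.value, mu, sigma)
        assert total_loglik(p, ds) == pytest.approx(plain, abs=1e-8)


class TestPriors:
    def test_phi_prior_mean_relation(self):
        pr = PriorSpec()
        assert pr.phi_log_mean == pytest.approx(-0.08, abs=1e-15)
        assert pr.phi_prior_expectation == pytest.approx(1.0, abs=1e-15)
        with pytest.raises(ValueError, match="expectation"):
            PriorSpec(phi_log_sd=0.4, phi_log_mean=0.0)

    def test_log_prior_closed_form_at_origin(self):
        p = _params(beta0=0.0)
        pr = PriorSpec()
        # 16 normal modes at 0 with sd 10; 35 free log-normal coordinates at 1
        expected = 16 * stats.norm.logpdf(0.0, 0, 10.0) + 35 * stats.lognorm.logpdf(
            1.0, s=0.4, scale=math.exp(-0.08)
        )
        assert log_prior(p, pr) == pytest.approx(expected, abs=1e-10)

    def test_doubling_sd_shifts_each_normal_term_by_log2(self):
        p = _params(beta0=0.0)
        narrow = log_prior(p, PriorSpec(beta_gamma_sd=10.0))
        wide = log_prior(p, PriorSpec(beta_gamma_sd=20.0))
        assert narrow - wide == pytest.approx(16 * math.log(2), abs=1e-10)

    def test_log_prior_rejects_broken_constraint(self):
        p = _params()
        p.phi = np.full((5, 8), 1.1)
        with pytest.raises(ValueError, match="mean-of-one"):
            log_prior(p, PriorSpec())
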