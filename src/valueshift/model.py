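"""Heteroskedastic Tobit likelihood with demographic preference-scale
parameters, and the corresponding prior densities.

The observed TTO value for respondent i in task t is a left-censored
version of a latent normal valuation::

    TTO_it = TTO*_it            if TTO*_it > -1
           = -1                 otherwise,            TTO*_it ~ N(mu_it, sigma_it)

The mean combines an intercept, ten dimension-level decrements
(MO2..AD3) and multiplicative sex/age scale parameters phi::

    mu_it = b0 + sum_d (b_d2 I_d2 + b_d3 I_d3) * phi_d[cell(i)]

and the standard deviation is a log-linear 4th-order polynomial in the
mean, so response noise can vary flexibly with state severity::

    sigma_it = exp(g0 + g1 mu + g2 mu^2 + g3 mu^3 + g4 mu^4)

For identification each dimension's phi vector is positive with
arithmetic mean one over the G demographic cells, so the betas carry
the population-average decrements and phi carries relative preference
weight.  Priors: N(0, 10) on betas and gammas; log-normal with
log-sd 0.4 and log-mean -0.08 (= -sd^2/2, prior expectation exactly 1)
on the free phi coordinates.

The likelihood only depends on the data through per-(state, cell)
sufficient statistics -- counts, sums and sums of squares of the
uncensored values plus censored counts -- so :class:`CompiledData`
aggregates a dataset once and evaluation cost is O(#states x #cells)
instead of O(#observations).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import log_ndtr

from .core import DECREMENT_LABELS, DIMENSIONS, DemographicCell, encode_state, standard_cells
from .io import ValuationDataset

_LOG_2PI = math.log(2.0 * math.pi)
MEAN_ONE_TOL = 1e-10
#: |log sigma| beyond this signals divergent variance parameters
_LOG_SD_LIMIT = 300.0


@dataclass
class PriorSpec:
    """Prior hyperparameters.

    ``phi_log_mean`` defaults to ``-phi_log_sd**2 / 2`` so the
    log-normal prior on each free scale parameter has expectation 1.
    """

    beta_gamma_sd: float = 10.0
    phi_log_sd: float = 0.4
    phi_log_mean: float | None = None

    def __post_init__(self) -> None:
        if self.phi_log_mean is None:
            self.phi_log_mean = -self.phi_log_sd**2 / 2.0
        if abs(self.phi_log_mean + self.phi_log_sd**2 / 2.0) > 1e-12:
            raise ValueError(
                "phi_log_mean must equal -phi_log_sd^2/2 so the prior has expectation 1"
            )
        if self.beta_gamma_sd <= 0 or self.phi_log_sd <= 0:
            raise ValueError("prior standard deviations must be positive")

    @property
    def phi_prior_expectation(self) -> float:
        return math.exp(self.phi_log_mean + self.phi_log_sd**2 / 2.0)


def phi_mean_one_ok(phi: np.ndarray, tol: float = MEAN_ONE_TOL) -> bool:
    """The identification predicate: unweighted cell-mean of each
    dimension's scale parameters equals 1.  Isolated here so a weighted
    variant would be a one-line change."""
    return bool(np.all(np.abs(phi.mean(axis=1) - 1.0) <= tol))


@dataclass
class ModelParams:
    """Full parameter state: intercept, 10 decrements, 5 variance
    coefficients and a (5, G) matrix of positive mean-one scale
    parameters over ``cells``."""

    beta0: float
    beta: np.ndarray
    gamma: np.ndarray
    phi: np.ndarray
    cells: tuple = field(default_factory=standard_cells)

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.gamma = np.asarray(self.gamma, dtype=float)
        self.phi = np.asarray(self.phi, dtype=float)
        self.cells = tuple(self.cells)
        if self.beta.shape != (10,):
            raise ValueError(f"beta must have shape (10,), got {self.beta.shape}")
        if self.gamma.shape != (5,):
            raise ValueError(f"gamma must have shape (5,), got {self.gamma.shape}")
        G = len(self.cells)
        if self.phi.shape != (5, G):
            raise ValueError(
                f"phi must have shape (5, {G}) for {G} cells, got {self.phi.shape}"
            )
        if np.any(self.phi <= 0):
            raise ValueError("all scale parameters phi must be positive")
        if not phi_mean_one_ok(self.phi):
            raise ValueError(
                "phi violates the mean-of-one constraint: cell means "
                f"{self.phi.mean(axis=1)}"
            )

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def cell_index(self, cell) -> int:
        try:
            return self.cells.index(cell)
        except ValueError:
            label = getattr(cell, "label", repr(cell))
            raise ValueError(f"cell {label} not among the model's cells") from None

    def copy(self) -> "ModelParams":
        return ModelParams(
            self.beta0, self.beta.copy(), self.gamma.copy(), self.phi.copy(), self.cells
        )


def linear_predictor(params: ModelParams, dummies, cell) -> float:
    """Mean valuation mu for one state (given as its indicator vector)
    and one demographic cell."""
    x = np.asarray(dummies, dtype=float)
    if x.shape != (10,):
        raise ValueError("dummies must be the length-10 indicator vector")
    g = params.cell_index(cell)
    mu = params.beta0
    for d in range(5):
        mu += (
            params.beta[2 * d] * x[2 * d] + params.beta[2 * d + 1] * x[2 * d + 1]
        ) * params.phi[d, g]
    return float(mu)


def scale_sd(params: ModelParams, mu: float) -> float:
    """Heteroskedastic SD: exp of a 4th-order polynomial in the mean."""
    if not np.isfinite(mu):
        raise ValueError("mu must be finite")
    g = params.gamma
    log_sd = g[0] + mu * (g[1] + mu * (g[2] + mu * (g[3] + mu * g[4])))
    if abs(log_sd) > _LOG_SD_LIMIT:
        raise ValueError(
            f"divergent variance parameters: |log sigma| = {abs(log_sd):.1f}"
        )
    return float(math.exp(log_sd))


def tobit_loglik_obs(value: float, mu: float, sigma: float, censor: float = -1.0) -> float:
    """Log-likelihood of one observation: normal density above the
    censoring point, normal CDF mass at it."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if value < censor:
        raise ValueError(f"value {value} below the censoring point {censor}")
    if value == censor:
        return float(log_ndtr((censor - mu) / sigma))
    z = (value - mu) / sigma
    return float(-0.5 * _LOG_2PI - math.log(sigma) - 0.5 * z * z)


# ---------------------------------------------------------------------------
# compiled data: per-(state, cell) sufficient statistics
# ---------------------------------------------------------------------------


@dataclass
class CompiledData:
    """Sufficient statistics of a QC-filtered dataset on the
    (distinct state) x (demographic cell) grid."""

    state_codes: tuple[str, ...]
    cells: tuple
    X: np.ndarray        # (S, 10) int8 indicators
    n_unc: np.ndarray    # (S, G) uncensored counts
    sum_v: np.ndarray    # (S, G) sums of uncensored values
    sum_v2: np.ndarray   # (S, G) sums of squared uncensored values
    n_cens: np.ndarray   # (S, G) censored counts
    n_observations: int = 0

    @classmethod
    def from_dataset(cls, dataset: ValuationDataset, cells=None) -> "CompiledData":
        cells = tuple(cells) if cells is not None else standard_cells()
        cell_idx = {c: i for i, c in enumerate(cells)}
        codes: dict[str, int] = {}
        triples = []  # (state index, cell index, value, censored)
        for r in dataset.respondents:
            if r.cell not in cell_idx:
                raise ValueError(
                    f"respondent {r.respondent_id} in cell {r.cell.label} "
                    "not covered by the model's cells"
                )
            g = cell_idx[r.cell]
            for obs in r.observations:
                s = codes.setdefault(obs.state.code, len(codes))
                triples.append((s, g, obs.value, obs.censored))
        S, G = len(codes), len(cells)
        X = np.zeros((S, 10), dtype=np.int8)
        for code, s in codes.items():
            X[s] = encode_state(code)
        n_unc = np.zeros((S, G))
        sum_v = np.zeros((S, G))
        sum_v2 = np.zeros((S, G))
        n_cens = np.zeros((S, G))
        for s, g, v, cens in triples:
            if cens:
                n_cens[s, g] += 1
            else:
                n_unc[s, g] += 1
                sum_v[s, g] += v
                sum_v2[s, g] += v * v
        ordered = sorted(codes, key=codes.get)
        return cls(tuple(ordered), cells, X, n_unc, sum_v, sum_v2, n_cens,
                   n_observations=len(triples))

    @classmethod
    def empty(cls, cells=None) -> "CompiledData":
        """A dataset with no observations (likelihood identically 0);
        used for prior-recovery runs."""
        cells = tuple(cells) if cells is not None else standard_cells()
        G = len(cells)
        z = np.zeros((0, G))
        return cls((), cells, np.zeros((0, 10), dtype=np.int8), z, z, z, z, 0)


def _mu_grid(beta0: float, beta: np.ndarray, phi: np.ndarray, X: np.ndarray) -> np.ndarray:
    # t[s, d] = beta_d2 * I_d2 + beta_d3 * I_d3 for state s, dimension d
    t = (X.reshape(-1, 5, 2) * beta.reshape(5, 2)).sum(axis=2)
    return beta0 + t @ phi


def loglik_grid(
    mu: np.ndarray,
    gamma: np.ndarray,
    n_unc: np.ndarray,
    sum_v: np.ndarray,
    sum_v2: np.ndarray,
    n_cens: np.ndarray,
    has_cens: bool = True,
) -> float:
    """Tobit log-likelihood over any slice of the (state, cell) grid,
    given the matching mean grid ``mu`` and sufficient statistics.

    Returns ``-inf`` for parameter values whose variance polynomial
    overflows, so samplers reject them instead of crashing.
    """
    g = gamma
    log_sd = g[0] + mu * (g[1] + mu * (g[2] + mu * (g[3] + mu * g[4])))
    if not np.all(np.abs(log_sd) < _LOG_SD_LIMIT):
        return -math.inf
    sigma = np.exp(log_sd)
    inv_2var = 0.5 / (sigma * sigma)
    ss = sum_v2 - 2.0 * mu * sum_v + n_unc * mu * mu
    total = float(np.sum(-n_unc * (log_sd + 0.5 * _LOG_2PI) - ss * inv_2var))
    if has_cens:
        z = (-1.0 - mu) / sigma
        total += float(np.sum(n_cens * log_ndtr(z)))
    return total if np.isfinite(total) else -math.inf


def loglik_arrays(
    beta0: float,
    beta: np.ndarray,
    gamma: np.ndarray,
    phi: np.ndarray,
    data: CompiledData,
) -> float:
    """Total Tobit log-likelihood from raw parameter arrays."""
    if data.n_observations == 0:
        return 0.0
    mu = _mu_grid(beta0, beta, phi, data.X)
    return loglik_grid(
        mu, gamma, data.n_unc, data.sum_v, data.sum_v2, data.n_cens,
        has_cens=bool(np.any(data.n_cens)),
    )


def total_loglik(params: ModelParams, data) -> float:
    """Total log-likelihood of a dataset (or pre-compiled data)."""
    if isinstance(data, ValuationDataset):
        data = CompiledData.from_dataset(data, params.cells)
    if data.cells != params.cells:
        raise ValueError("compiled data cells do not match the model's cells")
    return loglik_arrays(params.beta0, params.beta, params.gamma, params.phi, data)


# ---------------------------------------------------------------------------
# priors
# ---------------------------------------------------------------------------


def normal_logpdf(x: float, sd: float) -> float:
    return -0.5 * _LOG_2PI - math.log(sd) - 0.5 * (x / sd) ** 2


def lognormal_logpdf(x: float, log_mean: float, log_sd: float) -> float:
    if x <= 0:
        return -math.inf
    lx = math.log(x)
    return (
        -lx - math.log(log_sd) - 0.5 * _LOG_2PI
        - 0.5 * ((lx - log_mean) / log_sd) ** 2
    )


def log_prior(params: ModelParams, priors: PriorSpec | None = None) -> float:
    """Joint log prior density.

    Normal(0, ``beta_gamma_sd``) on the intercept, the ten decrements
    and the five variance coefficients; log-normal on the free phi
    coordinates.  The constraint is parameterized with G-1 free cells
    per dimension (the last cell is ``G - sum(others)``), and the prior
    is evaluated on the free coordinates only.
    """
    priors = priors or PriorSpec()
    if np.any(params.phi <= 0):
        raise ValueError("phi must be positive")
    if not phi_mean_one_ok(params.phi):
        raise ValueError("phi violates the mean-of-one constraint")
    sd = priors.beta_gamma_sd
    total = normal_logpdf(params.beta0, sd)
    total += sum(normal_logpdf(b, sd) for b in params.beta)
    total += sum(normal_logpdf(g, sd) for g in params.gamma)
    for d in range(5):
        for x in params.phi[d, :-1]:
            total += lognormal_logpdf(float(x), priors.phi_log_mean, priors.phi_log_sd)
    return float(total)


def log_posterior(params: ModelParams, data, priors: PriorSpec | None = None) -> float:
    return total_loglik(params, data) + log_prior(params, priors)


def labels_to_beta_index(label: str) -> int:
    """Map a decrement label like ``"PD3"`` to its beta index (0..9)."""
    try:
        return DECREMENT_LABELS.index(label)
    except ValueError:
        raise ValueError(f"unknown decrement label {label!r}") from None


def dimension_of_label(label: str) -> int:
    """Map a decrement label to its dimension index (0..4)."""
    return labels_to_beta_index(label) // 2
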