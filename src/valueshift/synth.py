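"""Synthetic TTO valuation studies with the statistical structure the
analysis assumes.

The generator draws respondents' sex/age cells i.i.d. from a survey
composition, assigns each respondent a task list in one of two design
dialects -- a fixed panel of 17 states valued by everyone (as in the
Japanese study) or a per-respondent random sample of 12 distinct
states from a fixed 45-state pool (as in the UK and US studies) --
then simulates latent valuations from the heteroskedastic Tobit model
and censors them at -1.  Because the latent model is normal, simulated
uncensored values can exceed 1; real surveys cannot produce such
values, but keeping the generative model identical to the fitted
likelihood is what makes parameter-recovery checks meaningful.

Two kinds of excludable respondents can be planted: low completers
(fewer than 10 tasks) and nonsense responders whose decrements are
sign-flipped, which guarantees a positively sloped value-vs-misery
relationship in expectation so the QC filter's target is unambiguous.

The published 45-state and 17-state designs are not reproduced here;
the pools below are synthetic stand-ins with matched cardinality,
including the worst state 33333 and spanning misery 6-15.  Users with
the real designs can inject them via ``TruthScenario.design_pool``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import (
    DemographicCell,
    HealthState,
    RespondentRecord,
    TTOObservation,
    standard_cells,
)
from .io import DemographicWeights, ValuationDataset, load_reference_weights
from .model import ModelParams

#: synthetic stand-in for a 45-state TTO design (misery 6-15, incl. 33333)
POOL_45: tuple[str, ...] = (
    "11212", "11233", "11313", "11322", "12111", "12113", "12122", "12222",
    "12223", "12312", "12322", "12323", "12333", "13112", "13122", "13132",
    "13133", "13233", "13331", "21112", "21223", "21313", "22112", "22121",
    "22221", "22311", "22331", "23211", "23222", "23311", "23332", "31111",
    "31132", "31211", "31213", "31312", "32212", "32221", "32222", "32232",
    "32313", "33213", "33223", "33332", "33333",
)

#: synthetic stand-in for a fixed 17-state panel (misery 6-15, incl. 33333)
POOL_17: tuple[str, ...] = (
    "11121", "11221", "13132", "13211", "13231", "21111", "21131", "21132",
    "22112", "22321", "23232", "23332", "31313", "32323", "33222", "33323",
    "33333",
)

# deviations from 1 with exact zero mean per dimension; max magnitude 0.25.
# Rough shapes: mobility and usual activities weigh more for older groups,
# self-care and pain/anxiety more for younger ones.
_PHI_DEVIATIONS = np.array(
    [
        [-0.20, -0.10, 0.10, 0.25, -0.25, -0.05, 0.10, 0.15],  # MO
        [0.10, 0.05, -0.05, -0.25, 0.25, 0.05, -0.10, -0.05],  # SC
        [-0.15, -0.05, 0.05, 0.15, -0.15, -0.05, 0.05, 0.15],  # UA
        [0.20, 0.10, -0.10, -0.20, 0.25, 0.05, -0.10, -0.20],  # PD
        [0.25, 0.10, -0.05, -0.25, 0.20, 0.05, -0.10, -0.20],  # AD
    ]
)

# decrements anchored near each country's published original value set
_COUNTRY_BETA = {
    "UK": (-0.06, -0.34, -0.11, -0.23, -0.08, -0.22, -0.09, -0.47, -0.12, -0.37),
    "JPN": (-0.10, -0.43, -0.05, -0.09, -0.03, -0.13, -0.06, -0.18, -0.06, -0.12),
    "US": (-0.04, -0.34, -0.07, -0.24, -0.04, -0.17, -0.05, -0.36, -0.08, -0.26),
}

_COUNTRY_STYLE = {
    # (sample composition label, dialect, pre-QC respondents,
    #  low-completer fraction, positive-slope fraction)
    "UK": ("UK-sample", "sampled-12-of-45", 3395, 82 / 3395, 43 / 3395),
    "JPN": ("JPN-sample", "fixed-17", 543, 3 / 543, 4 / 543),
    "US": ("US-sample", "sampled-12-of-45", 4048, 0.0, 133 / 4048),
}

#: mild heteroskedasticity: sigma ~ 0.20 at mu = 1 up to ~ 0.40 at mu = -0.5
_DEFAULT_GAMMA = (-1.2, -0.5, 0.1, 0.0, 0.0)
_DEFAULT_BETA0 = 0.95


@dataclass
class TruthScenario:
    """True parameters and study design for one simulated TTO study."""

    params: ModelParams
    composition: DemographicWeights
    design_dialect: str  # "fixed-17" or "sampled-12-of-45"
    n_respondents: int
    frac_low_completers: float = 0.0
    frac_positive_slope: float = 0.0
    seed: int | None = None
    design_pool: tuple[str, ...] | None = None
    tasks_per_respondent: int = 12

    def __post_init__(self) -> None:
        if self.design_dialect not in ("fixed-17", "sampled-12-of-45"):
            raise ValueError(f"unknown design dialect {self.design_dialect!r}")
        for frac in (self.frac_low_completers, self.frac_positive_slope):
            if not 0.0 <= frac < 1.0:
                raise ValueError("contamination fractions must be in [0, 1)")
        if self.n_respondents < 1:
            raise ValueError("need at least one respondent")
        if self.design_pool is None:
            self.design_pool = (
                POOL_17 if self.design_dialect == "fixed-17" else POOL_45
            )

    @property
    def n_planted_low(self) -> int:
        return int(round(self.frac_low_completers * self.n_respondents))

    @property
    def n_planted_positive(self) -> int:
        return int(round(self.frac_positive_slope * self.n_respondents))


def default_truth(
    country_style: str,
    n_respondents: int | None = None,
    seed: int | None = None,
    contaminate: bool = True,
) -> TruthScenario:
    """A plausible truth for a UK-, JPN- or US-style study.

    Decrements sit near the country's published value set, the
    intercept near full health, noise is mildly heteroskedastic, scale
    parameters vary by up to +-25% across the 8 sex/age cells, and the
    respondent composition is the corresponding survey sample's.
    """
    if country_style not in _COUNTRY_BETA:
        raise ValueError(
            f"unknown country style {country_style!r}; expected UK, JPN or US"
        )
    comp_label, dialect, n_default, f_low, f_pos = _COUNTRY_STYLE[country_style]
    cells = standard_cells()
    params = ModelParams(
        _DEFAULT_BETA0,
        np.array(_COUNTRY_BETA[country_style]),
        np.array(_DEFAULT_GAMMA),
        1.0 + _PHI_DEVIATIONS.copy(),
        cells,
    )
    return TruthScenario(
        params=params,
        composition=load_reference_weights(comp_label),
        design_dialect=dialect,
        n_respondents=n_respondents if n_respondents is not None else n_default,
        frac_low_completers=f_low if contaminate else 0.0,
        frac_positive_slope=f_pos if contaminate else 0.0,
        seed=seed,
    )


def make_design(
    dialect: str,
    n_respondents: int,
    rng: np.random.Generator,
    pool: tuple[str, ...] | None = None,
    n_tasks: int = 12,
) -> list[list[str]]:
    """Task lists per respondent.

    ``fixed-17``: everyone values the same 17 states.
    ``sampled-12-of-45``: each respondent values ``n_tasks`` distinct
    states sampled from the 45-state pool, one per severity stratum
    (the pool sorted by misery index and split into ``n_tasks``
    consecutive blocks).  Stratification mirrors how TTO designs are
    built in practice -- every respondent values states across the
    whole severity range -- and keeps the value-vs-misery slope used
    by the QC filter well identified for each respondent.
    """
    if dialect == "fixed-17":
        pool = tuple(pool) if pool is not None else POOL_17
        return [list(pool) for _ in range(n_respondents)]
    if dialect == "sampled-12-of-45":
        pool = tuple(pool) if pool is not None else POOL_45
        if n_tasks > len(pool):
            raise ValueError("more tasks than states in the pool")
        by_severity = sorted(pool, key=lambda c: (sum(int(ch) for ch in c), c))
        strata = np.array_split(np.array(by_severity), n_tasks)
        return [
            [str(stratum[rng.integers(len(stratum))]) for stratum in strata]
            for _ in range(n_respondents)
        ]
    raise ValueError(f"unknown design dialect {dialect!r}")


def _mu_sigma(params: ModelParams, state: HealthState, cell_index: int):
    x = state.dummies().astype(float)
    mu = params.beta0
    for d in range(5):
        mu += (
            params.beta[2 * d] * x[2 * d] + params.beta[2 * d + 1] * x[2 * d + 1]
        ) * params.phi[d, cell_index]
    g = params.gamma
    log_sd = g[0] + mu * (g[1] + mu * (g[2] + mu * (g[3] + mu * g[4])))
    return mu, math.exp(log_sd)


def simulate_study(
    truth: TruthScenario, rng: np.random.Generator | None = None, audit: bool = False
):
    """Simulate one study from the generative Tobit model.

    Returns the :class:`ValuationDataset`, or with ``audit=True`` a
    ``(dataset, audit)`` pair where the audit dict lists the planted
    low-completer and sign-flipped respondent ids.
    """
    if rng is None:
        rng = np.random.default_rng(truth.seed)
    params = truth.params
    cells = params.cells
    shares = truth.composition.aligned(cells)
    n = truth.n_respondents

    designs = make_design(
        truth.design_dialect, n, rng, truth.design_pool, truth.tasks_per_respondent
    )
    cell_draws = rng.choice(len(cells), size=n, p=shares)

    order = rng.permutation(n)
    low_ids = set(order[: truth.n_planted_low])
    pos_ids = set(
        order[truth.n_planted_low: truth.n_planted_low + truth.n_planted_positive]
    )
    flipped = params.copy()
    flipped.beta = -flipped.beta

    width = len(str(n))
    respondents = []
    audit_info = {"low_completers": [], "positive_slope": []}
    for i in range(n):
        rid = f"R{i + 1:0{width}d}"
        g = int(cell_draws[i])
        tasks = designs[i]
        p = params
        if i in pos_ids:
            p = flipped
            audit_info["positive_slope"].append(rid)
        if i in low_ids:
            tasks = tasks[: int(rng.integers(1, 10))]
            audit_info["low_completers"].append(rid)
        obs = []
        for code in tasks:
            state = HealthState(code)
            mu, sigma = _mu_sigma(p, state, g)
            latent = rng.normal(mu, sigma)
            value = -1.0 if latent <= -1.0 else float(latent)
            obs.append(TTOObservation(rid, state, value))
        respondents.append(RespondentRecord(rid, cells[g], obs))
    dataset = ValuationDataset(
        respondents,
        design_dialect=truth.design_dialect,
        provenance=f"synthetic (seed={truth.seed})",
    )
    return (dataset, audit_info) if audit else dataset


def censoring_rate(dataset: ValuationDataset) -> float:
    """Fraction of observations censored at -1; ``nan`` for an empty
    dataset (undefined)."""
    n = dataset.n_observations
    if n == 0:
        return float("nan")
    return sum(obs.censored for _, obs in dataset.iter_observations()) / n
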