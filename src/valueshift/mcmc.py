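"""Posterior sampling for the heteroskedastic Tobit model.

A systematic-scan Metropolis-within-Gibbs sampler: the intercept, the
ten decrements and the five variance coefficients are updated one at a
time with Gaussian random-walk proposals.  Antithetic sampling is
implemented as antithetically *coupled chain pairs*: the second chain
of a pair is driven by the mirror image of the first chain's random
stream (every proposal innovation negated, ``u`` and ``-u`` mirrored
pairs; every acceptance uniform reflected to ``1 - u``).  Each chain
is therefore a marginally exact sampler -- correctness never depends
on the coupling -- while the negative correlation between paired
chains reduces the Monte-Carlo variance of pooled posterior averages.
(Mirroring innovations *within* a single chain's successive updates
is tempting but breaks stationarity, which is measurable in
prior-recovery runs; hence the across-chain construction.)

Each dimension's
scale parameters are updated by univariate stepping-out/shrinkage slice
sampling on the G-1 free coordinates, with the last cell defined as
``G - sum(others)`` so the positivity and mean-one constraints hold
exactly at every draw.

Step sizes are tuned by Robbins-Monro adaptation toward a 0.44
acceptance rate during burn-in and frozen afterwards, so the retained
chain is a valid time-homogeneous sampler.  All randomness flows from
explicit seeds through per-chain ``numpy`` generator streams.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import DECREMENT_LABELS, DIMENSIONS, standard_cells
from .io import ValuationDataset
from .model import (
    CompiledData,
    ModelParams,
    PriorSpec,
    lognormal_logpdf,
    loglik_arrays,
    loglik_grid,
    normal_logpdf,
)

_TARGET_ACCEPT = 0.44


@dataclass
class MCMCConfig:
    """Sampler settings.  ``n_total`` counts all iterations including
    burn-in, so ``n_total - n_burnin`` draws are retained per chain."""

    n_chains: int = 3
    n_burnin: int = 10_000
    n_total: int = 30_000
    thin: int = 1
    seed: int = 0
    step_beta0: float = 0.02
    step_beta: float = 0.05
    step_gamma: float = 0.1
    slice_w: float = 0.25
    antithetic: bool = True
    adapt: bool = True

    def __post_init__(self) -> None:
        if not self.n_total > self.n_burnin >= 0:
            raise ValueError("need n_total > n_burnin >= 0")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.n_chains < 1:
            raise ValueError("need at least one chain")

    @property
    def n_retained(self) -> int:
        return (self.n_total - self.n_burnin) // self.thin


class AntitheticRNG:
    """Mirror image of a ``numpy`` generator stream.

    Standard-normal draws are negated and acceptance uniforms are
    reflected (``u -> 1 - u``), so innovations from a generator and its
    mirror form pairs ``(z, -z)`` summing to zero exactly, while each
    stream taken alone has exactly the right marginal law.  Driving one
    chain of a pair with the mirror of the other's seed yields
    antithetically coupled, individually valid chains.
    """

    def __init__(self, seed):
        self._rng = np.random.default_rng(seed)

    def standard_normal(self, *args, **kwargs):
        return -self._rng.standard_normal(*args, **kwargs)

    def uniform(self):
        return 1.0 - self._rng.uniform()

    def exponential(self, *args, **kwargs):
        return self._rng.exponential(*args, **kwargs)

    def normal(self, *args, **kwargs):
        return -self._rng.normal(*args, **kwargs)

    def choice(self, *args, **kwargs):
        return self._rng.choice(*args, **kwargs)

    def integers(self, *args, **kwargs):
        return self._rng.integers(*args, **kwargs)

    def permutation(self, *args, **kwargs):
        return self._rng.permutation(*args, **kwargs)


def mh_update_scalar(current, logpost, step, rng):
    """One Gaussian random-walk Metropolis update of a scalar.

    Returns ``(new_value, accepted)``.  ``rng`` may be a plain
    generator or an :class:`AntitheticRNG` mirror.
    """
    lp0 = logpost(current)
    if not np.isfinite(lp0):
        raise ValueError("log posterior is not finite at the current value")
    z = float(rng.standard_normal())
    proposal = current + step * z
    lp1 = logpost(proposal)
    if math.log(rng.uniform()) < lp1 - lp0:
        return proposal, True
    return current, False


def _slice_scalar(x0, f, y, w, rng, lo, hi, max_expand=10_000):
    """Stepping-out/shrinkage slice update of one coordinate, with the
    target truncated to the open interval (lo, hi)."""
    u = rng.uniform()
    left = x0 - w * u
    right = left + w
    n = 0
    while left > lo and f(left) > y:
        left -= w
        n += 1
        if n > max_expand:
            raise RuntimeError("slice sampler failed to bracket (left expansion)")
    while right < hi and f(right) > y:
        right += w
        n += 1
        if n > max_expand:
            raise RuntimeError("slice sampler failed to bracket (right expansion)")
    left = max(left, lo)
    right = min(right, hi)
    while True:
        x1 = left + rng.uniform() * (right - left)
        if f(x1) > y:
            return x1
        if x1 < x0:
            left = x1
        else:
            right = x1
        if right - left < 1e-300:
            raise RuntimeError("slice interval shrank to zero width")


def slice_update_phi(phi_free, logpost, w, rng, total=None):
    """Slice-sample each free coordinate of one dimension's scale
    vector, keeping all implied cells (including the derived one)
    positive.  ``total`` is the constrained sum (G by default)."""
    x = np.asarray(phi_free, dtype=float).copy()
    if total is None:
        total = float(len(x) + 1)
    derived = total - x.sum()
    if derived <= 0 or np.any(x <= 0):
        raise ValueError("current free coordinates violate positivity")
    for j in range(len(x)):
        xj = x[j]
        hi = xj + derived  # derived cell hits 0 at this value

        def f(v, j=j):
            if v <= 0.0 or v >= hi:
                return -math.inf
            x[j] = v
            out = logpost(x)
            x[j] = xj
            return out

        y = logpost(x) - rng.exponential()
        xnew = _slice_scalar(xj, f, y, w, rng, 0.0, hi)
        x[j] = xnew
        derived = total - x.sum()
    return x


# ---------------------------------------------------------------------------
# draws container
# ---------------------------------------------------------------------------


def _phi_param_name(d: int, cell) -> str:
    label = getattr(cell, "label", str(cell))
    return f"phi[{DIMENSIONS[d]}][{label}]"


@dataclass
class PosteriorDraws:
    """Retained draws for one or more chains, plus bookkeeping."""

    beta0: np.ndarray            # (C, T)
    beta: np.ndarray             # (C, T, 10)
    gamma: np.ndarray            # (C, T, 5)
    phi: np.ndarray              # (C, T, 5, G)
    cells: tuple
    monitored: dict[str, np.ndarray] = field(default_factory=dict)  # name -> (C, T)
    accept_rates: list[dict] = field(default_factory=list)
    step_sizes: list[dict] = field(default_factory=list)

    @property
    def n_chains(self) -> int:
        return self.beta0.shape[0]

    @property
    def n_draws(self) -> int:
        return self.beta0.shape[1]

    def parameter_names(self) -> list[str]:
        names = ["beta0"]
        names += [f"beta[{lab}]" for lab in DECREMENT_LABELS]
        names += [f"gamma[{k}]" for k in range(5)]
        names += [
            _phi_param_name(d, c) for d in range(5) for c in self.cells
        ]
        return names

    def parameter(self, name: str) -> np.ndarray:
        """Draws of one named parameter as a (chains, draws) array."""
        if name == "beta0":
            return self.beta0
        if name.startswith("beta[") and name.endswith("]"):
            return self.beta[:, :, DECREMENT_LABELS.index(name[5:-1])]
        if name.startswith("gamma[") and name.endswith("]"):
            return self.gamma[:, :, int(name[6:-1])]
        if name.startswith("phi["):
            dim, cell_label = name[4:-1].split("][")
            d = DIMENSIONS.index(dim)
            labels = [getattr(c, "label", str(c)) for c in self.cells]
            return self.phi[:, :, d, labels.index(cell_label)]
        if name in self.monitored:
            return self.monitored[name]
        raise KeyError(f"unknown parameter {name!r}")

    def params_at(self, chain: int, draw: int) -> ModelParams:
        return ModelParams(
            float(self.beta0[chain, draw]),
            self.beta[chain, draw].copy(),
            self.gamma[chain, draw].copy(),
            self.phi[chain, draw].copy(),
            self.cells,
        )

    def to_flat_table(self) -> pd.DataFrame:
        """Flat (chain, draw, parameter, value) table for storage."""
        frames = []
        for name in self.parameter_names():
            arr = self.parameter(name)
            C, T = arr.shape
            frames.append(
                pd.DataFrame(
                    {
                        "chain": np.repeat(np.arange(C), T),
                        "draw": np.tile(np.arange(T), C),
                        "parameter": name,
                        "value": arr.reshape(-1),
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)

    @classmethod
    def from_flat_table(cls, df: pd.DataFrame, cells=None) -> "PosteriorDraws":
        cells = tuple(cells) if cells is not None else standard_cells()
        G = len(cells)
        chains = np.sort(df["chain"].unique())
        draws = np.sort(df["draw"].unique())
        C, T = len(chains), len(draws)
        wide = df.pivot_table(
            index=["chain", "draw"], columns="parameter", values="value", sort=True
        )
        beta0 = wide["beta0"].to_numpy().reshape(C, T)
        beta = np.stack(
            [wide[f"beta[{lab}]"].to_numpy().reshape(C, T) for lab in DECREMENT_LABELS],
            axis=-1,
        )
        gamma = np.stack(
            [wide[f"gamma[{k}]"].to_numpy().reshape(C, T) for k in range(5)], axis=-1
        )
        phi = np.zeros((C, T, 5, G))
        for d in range(5):
            for g, cell in enumerate(cells):
                phi[:, :, d, g] = (
                    wide[_phi_param_name(d, cell)].to_numpy().reshape(C, T)
                )
        return cls(beta0, beta, gamma, phi, cells)

    @classmethod
    def stack(cls, chains: list["PosteriorDraws"]) -> "PosteriorDraws":
        first = chains[0]
        monitored = {
            k: np.concatenate([c.monitored[k] for c in chains], axis=0)
            for k in first.monitored
        }
        return cls(
            np.concatenate([c.beta0 for c in chains], axis=0),
            np.concatenate([c.beta for c in chains], axis=0),
            np.concatenate([c.gamma for c in chains], axis=0),
            np.concatenate([c.phi for c in chains], axis=0),
            first.cells,
            monitored,
            sum((c.accept_rates for c in chains), []),
            sum((c.step_sizes for c in chains), []),
        )


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------


def initialize_params(
    data, rng: np.random.Generator, cells=None, jitter: float = 0.01
) -> ModelParams:
    """Crude but valid starting values: least squares of the uncensored
    values on the state indicators for the betas, the log residual SD
    for gamma0, scale parameters near 1.  Jitter overdisperses starting
    points across chains."""
    if isinstance(data, ValuationDataset):
        data = CompiledData.from_dataset(data, cells)
    cells = data.cells
    G = len(cells)
    n_s = data.n_unc.sum(axis=1)
    if n_s.sum() == 0:
        raise ValueError("no uncensored observations: cannot initialize")
    D = np.hstack([np.ones((data.X.shape[0], 1)), data.X.astype(float)])
    A = (D * n_s[:, None]).T @ D
    b = D.T @ data.sum_v.sum(axis=1)
    coef, *_ = np.linalg.lstsq(A, b, rcond=None)
    rss = float(data.sum_v2.sum() - coef @ b)
    n_tot = float(n_s.sum())
    resid_sd = math.sqrt(max(rss, 1e-12) / max(n_tot - 11.0, 1.0))
    beta0 = float(coef[0] + jitter * rng.standard_normal())
    beta = coef[1:] + jitter * rng.standard_normal(10)
    gamma = np.zeros(5)
    gamma[0] = math.log(max(resid_sd, 1e-3)) + 5 * jitter * rng.standard_normal()
    free = np.clip(1.0 + 3 * jitter * rng.standard_normal(G - 1), 0.5, 1.5)
    phi_row = np.concatenate([free, [G - free.sum()]])
    phi = np.tile(phi_row, (5, 1))
    # re-enforce the constraint exactly per dimension
    phi[:, -1] = G - phi[:, :-1].sum(axis=1)
    return ModelParams(beta0, beta, gamma, phi, cells)


# ---------------------------------------------------------------------------
# the chain
# ---------------------------------------------------------------------------


class _Block:
    __slots__ = ("step", "n_prop", "n_acc", "t")

    def __init__(self, step: float):
        self.step = step
        self.n_prop = 0
        self.n_acc = 0
        self.t = 0

    def adapt(self, accepted: bool) -> None:
        self.t += 1
        gain = (self.t + 10.0) ** -0.6
        self.step = float(
            math.exp(math.log(self.step) + gain * ((1.0 if accepted else 0.0) - _TARGET_ACCEPT))
        )


def run_chain(
    data,
    config: MCMCConfig,
    chain_seed=None,
    init: ModelParams | None = None,
    priors: PriorSpec | None = None,
    monitors: dict | None = None,
    rng: np.random.Generator | None = None,
) -> PosteriorDraws:
    """Run one chain and return its retained draws (C=1)."""
    if isinstance(data, ValuationDataset):
        data = CompiledData.from_dataset(data)
    priors = priors or PriorSpec()
    if rng is None:
        rng = np.random.default_rng(chain_seed)
    if init is None:
        init = initialize_params(data, rng)
    cells = init.cells
    if data.cells != cells:
        raise ValueError("compiled data cells do not match the initial parameters")
    G = len(cells)

    beta0 = float(init.beta0)
    beta = init.beta.copy()
    gamma = init.gamma.copy()
    phi = init.phi.copy()
    sd = priors.beta_gamma_sd

    # incremental likelihood state: the (S, G) mean grid is maintained
    # across updates, and phi moves only touch two of its columns.
    S = data.X.shape[0]
    empty = data.n_observations == 0
    Xf = data.X.astype(float)
    t_mat = (Xf.reshape(S, 5, 2) * beta.reshape(5, 2)).sum(axis=2)  # (S, 5)
    mu = beta0 + t_mat @ phi if not empty else np.zeros((S, G))
    has_cens = bool(np.any(data.n_cens))

    def full_ll(mu_grid, gamma_vec):
        if empty:
            return 0.0
        return loglik_grid(
            mu_grid, gamma_vec, data.n_unc, data.sum_v, data.sum_v2,
            data.n_cens, has_cens,
        )

    # per-coordinate column pairs (free cell j, derived last cell)
    pair_stats = []
    for j in range(G - 1):
        cols = [j, G - 1]
        pair_stats.append(
            (
                np.ascontiguousarray(data.n_unc[:, cols]),
                np.ascontiguousarray(data.sum_v[:, cols]),
                np.ascontiguousarray(data.sum_v2[:, cols]),
                np.ascontiguousarray(data.n_cens[:, cols]),
                bool(np.any(data.n_cens[:, cols])),
            )
        )

    def pair_ll(j, mu_pair, gamma_vec):
        if empty:
            return 0.0
        nu, sv, sv2, nc, hc = pair_stats[j]
        return loglik_grid(mu_pair, gamma_vec, nu, sv, sv2, nc, hc)

    ll = full_ll(mu, gamma)
    if not np.isfinite(ll):
        raise ValueError("non-finite log posterior at initialization (likelihood)")

    blocks = {"beta0": _Block(config.step_beta0)}
    for j in range(10):
        blocks[f"beta[{DECREMENT_LABELS[j]}]"] = _Block(config.step_beta)
    for k in range(5):
        blocks[f"gamma[{k}]"] = _Block(config.step_gamma)

    T = config.n_retained
    out_beta0 = np.empty((1, T))
    out_beta = np.empty((1, T, 10))
    out_gamma = np.empty((1, T, 5))
    out_phi = np.empty((1, T, 5, G))
    monitors = monitors or {}
    out_mon = {name: np.empty((1, T)) for name in monitors}

    log_u = lambda: math.log(rng.uniform())

    stored = 0
    for it in range(config.n_total):
        adapting = it < config.n_burnin

        # periodic refresh of the incremental state against float drift
        if it % 200 == 0 and not empty:
            phi[:, -1] = G - phi[:, :-1].sum(axis=1)
            t_mat = (Xf.reshape(S, 5, 2) * beta.reshape(5, 2)).sum(axis=2)
            mu = beta0 + t_mat @ phi
            ll = full_ll(mu, gamma)

        # intercept
        blk = blocks["beta0"]
        prop = beta0 + blk.step * float(rng.standard_normal())
        mu_p = mu + (prop - beta0)
        new_ll = full_ll(mu_p, gamma)
        delta = (new_ll - ll) - 0.5 * (prop * prop - beta0 * beta0) / (sd * sd)
        accepted = np.isfinite(new_ll) and log_u() < delta
        blk.n_prop += 1
        if accepted:
            blk.n_acc += 1
            beta0, mu, ll = prop, mu_p, new_ll
        if adapting and config.adapt:
            blk.adapt(accepted)

        # decrements
        for j in range(10):
            d = j // 2
            blk = blocks[f"beta[{DECREMENT_LABELS[j]}]"]
            prop = beta[j] + blk.step * float(rng.standard_normal())
            db = prop - beta[j]
            mu_p = mu + db * Xf[:, j, None] * phi[d][None, :]
            new_ll = full_ll(mu_p, gamma)
            delta = (new_ll - ll) - 0.5 * (prop * prop - beta[j] * beta[j]) / (sd * sd)
            accepted = np.isfinite(new_ll) and log_u() < delta
            blk.n_prop += 1
            if accepted:
                blk.n_acc += 1
                t_mat[:, d] += db * Xf[:, j]
                beta[j], mu, ll = prop, mu_p, new_ll
            if adapting and config.adapt:
                blk.adapt(accepted)

        # variance polynomial
        for k in range(5):
            blk = blocks[f"gamma[{k}]"]
            prop = gamma[k] + blk.step * float(rng.standard_normal())
            gamma_p = gamma.copy()
            gamma_p[k] = prop
            new_ll = full_ll(mu, gamma_p)
            delta = (new_ll - ll) - 0.5 * (prop * prop - gamma[k] * gamma[k]) / (sd * sd)
            accepted = np.isfinite(new_ll) and log_u() < delta
            blk.n_prop += 1
            if accepted:
                blk.n_acc += 1
                gamma, ll = gamma_p, new_ll
            if adapting and config.adapt:
                blk.adapt(accepted)

        # scale parameters: slice-sample each free coordinate; the
        # derived last cell keeps the mean-one constraint exact and
        # only two columns of the mean grid move per coordinate.
        for d in range(5):
            td = t_mat[:, d]
            for j in range(G - 1):
                xj = float(phi[d, j])
                last = float(phi[d, G - 1])
                hi = xj + last
                base_pair = np.ascontiguousarray(mu[:, [j, G - 1]])
                ll_pair_cur = pair_ll(j, base_pair, gamma)
                lp_cur = lognormal_logpdf(xj, priors.phi_log_mean, priors.phi_log_sd)
                cache = {"v": ll_pair_cur, "x": xj}

                def f(x, j=j, xj=xj, hi=hi, base_pair=base_pair, td=td):
                    if x <= 0.0 or x >= hi:
                        return -math.inf
                    mp = base_pair + np.outer(td, (x - xj, xj - x))
                    v = pair_ll(j, mp, gamma)
                    cache["v"], cache["x"] = v, x
                    return v + lognormal_logpdf(
                        x, priors.phi_log_mean, priors.phi_log_sd
                    )

                y = ll_pair_cur + lp_cur - rng.exponential()
                xnew = _slice_scalar(xj, f, y, config.slice_w, rng, 0.0, hi)
                if xnew != xj:
                    phi[d, j] = xnew
                    phi[d, G - 1] = last + (xj - xnew)
                    mu[:, j] += td * (xnew - xj)
                    mu[:, G - 1] += td * (xj - xnew)
                    assert cache["x"] == xnew
                    ll = ll - ll_pair_cur + cache["v"]

        if it >= config.n_burnin and (it - config.n_burnin) % config.thin == 0:
            if stored < T:
                out_beta0[0, stored] = beta0
                out_beta[0, stored] = beta
                out_gamma[0, stored] = gamma
                out_phi[0, stored] = phi
                if monitors:
                    p = ModelParams(beta0, beta.copy(), gamma.copy(), phi.copy(), cells)
                    for name, fn in monitors.items():
                        out_mon[name][0, stored] = fn(p)
                stored += 1

    acc = {
        name: (blk.n_acc / blk.n_prop if blk.n_prop else float("nan"))
        for name, blk in blocks.items()
    }
    steps = {name: blk.step for name, blk in blocks.items()}
    return PosteriorDraws(
        out_beta0, out_beta, out_gamma, out_phi, cells, out_mon, [acc], [steps]
    )


def fit(
    dataset,
    config: MCMCConfig,
    priors: PriorSpec | None = None,
    cells=None,
    monitors: dict | None = None,
    inits: list[ModelParams] | None = None,
) -> PosteriorDraws:
    """Fit the model with ``config.n_chains`` chains from one master
    seed, overdispersed starting points, and stacked retained draws."""
    if isinstance(dataset, ValuationDataset):
        data = CompiledData.from_dataset(dataset, cells)
    else:
        data = dataset
    master = np.random.SeedSequence(config.seed)
    if config.antithetic:
        # chains come in antithetically coupled pairs sharing one seed:
        # the odd chain of each pair runs on the mirror stream
        pair_seeds = master.spawn((config.n_chains + 1) // 2)
        rngs = [
            AntitheticRNG(pair_seeds[c // 2]) if c % 2 == 1
            else np.random.default_rng(pair_seeds[c // 2])
            for c in range(config.n_chains)
        ]
    else:
        rngs = [np.random.default_rng(s) for s in master.spawn(config.n_chains)]
    chains = []
    for c in range(config.n_chains):
        rng = rngs[c]
        init = inits[c] if inits is not None else initialize_params(data, rng)
        chains.append(
            run_chain(
                data, config, init=init, priors=priors, monitors=monitors, rng=rng
            )
        )
    return PosteriorDraws.stack(chains)


# ---------------------------------------------------------------------------
# convergence diagnostics
# ---------------------------------------------------------------------------


def gelman_rubin(draws, parameter: str | None = None) -> float:
    """Split-chain potential scale reduction factor (R-hat).

    Accepts a :class:`PosteriorDraws` plus a parameter name, or a raw
    (chains, draws) array.  Chains are split in half, so ``m = 2C``
    sequences enter the between/within variance decomposition.  Returns
    ``nan`` when within-chain variance vanishes everywhere.
    """
    arr = draws.parameter(parameter) if isinstance(draws, PosteriorDraws) else np.asarray(draws, float)
    if arr.ndim != 2:
        raise ValueError("expected a (chains, draws) array")
    C, T = arr.shape
    if C < 2:
        raise ValueError("R-hat needs at least 2 chains")
    if T < 10:
        raise ValueError("R-hat needs at least 10 retained draws per chain")
    half = T // 2
    split = np.concatenate([arr[:, :half], arr[:, half: 2 * half]], axis=0)
    n = half
    means = split.mean(axis=1)
    variances = split.var(axis=1, ddof=1)
    W = variances.mean()
    if W == 0.0:
        return float("nan")
    B = n * means.var(ddof=1)
    var_plus = (n - 1) / n * W + B / n
    return float(math.sqrt(var_plus / W))


def rhat_table(draws: PosteriorDraws) -> dict[str, float]:
    """R-hat for every model parameter."""
    return {name: gelman_rubin(draws, name) for name in draws.parameter_names()}
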