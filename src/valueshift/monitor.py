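"""Demographically weighted value sets and their difference.

A value set's decrement for, say, PD3 under a population composition
``w`` is the population-average of the cell-specific decrements::

    D_PD3(w) = sum_c w_c * beta_PD3 * phi_PD[c] = beta_PD3 * (w . phi_PD)

Evaluating this per posterior draw under the composition at the time of
data collection ("original") and under a later composition ("updated")
yields the posterior of both value sets and -- the quantity of interest
-- of their difference.  The difference is reported as
``updated - original``; note that published tables sometimes print the
change in decrement *magnitude* (a positive entry meaning the decrement
grew more negative), which is the negative of this raw signed
difference for negative decrements.

Monitoring is computed post hoc on stored draws (the canonical path,
decoupling fitting from weighting); :func:`make_valueset_monitors`
builds inline per-draw monitors that produce bit-identical values
during sampling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import DECREMENT_LABELS, HealthState, encode_state
from .io import DemographicWeights, VALUESET_COLUMNS
from .mcmc import PosteriorDraws
from .model import ModelParams, dimension_of_label


def weighted_decrement(beta_dl: float, phi_d, weights, cells=None) -> float:
    """Population-weighted decrement for one dimension-level.

    ``weights`` is either a share vector already aligned with
    ``phi_d`` or a :class:`DemographicWeights` together with the
    ``cells`` ordering of ``phi_d``."""
    phi_d = np.asarray(phi_d, dtype=float)
    if isinstance(weights, DemographicWeights):
        if cells is None:
            raise ValueError("cells ordering required with DemographicWeights")
        w = weights.aligned(cells)
    else:
        w = np.asarray(weights, dtype=float)
    if w.shape != phi_d.shape:
        raise ValueError("weights and phi vectors must align")
    return float(beta_dl * (phi_d @ w))


@dataclass
class ValueSetDraws:
    """Per-draw weighted decrements under two compositions.

    Arrays have shape (chains, draws, 10) in :data:`DECREMENT_LABELS`
    order; ``diff = updated - original`` exactly, per draw.
    """

    labels: tuple[str, ...]
    original: np.ndarray
    updated: np.ndarray
    diff: np.ndarray
    weights_original_label: str = ""
    weights_updated_label: str = ""

    @property
    def n_draws_total(self) -> int:
        return self.original.shape[0] * self.original.shape[1]


def _weighted_phi(phi: np.ndarray, w: np.ndarray) -> np.ndarray:
    # multiply-then-sum (not matmul) so per-draw recomputation with the
    # same expression is bit-identical to this vectorized path
    return (phi * w).sum(axis=-1)


def monitor_valuesets(
    draws: PosteriorDraws,
    weights_original: DemographicWeights,
    weights_updated: DemographicWeights,
) -> ValueSetDraws:
    """Compute both value sets and their difference for every draw."""
    w_o = weights_original.aligned(draws.cells)
    w_u = weights_updated.aligned(draws.cells)
    wphi_o = _weighted_phi(draws.phi, w_o)  # (C, T, 5)
    wphi_u = _weighted_phi(draws.phi, w_u)
    dims = np.array([dimension_of_label(lab) for lab in DECREMENT_LABELS])
    original = draws.beta * wphi_o[:, :, dims]
    updated = draws.beta * wphi_u[:, :, dims]
    return ValueSetDraws(
        DECREMENT_LABELS,
        original,
        updated,
        updated - original,
        weights_original.label,
        weights_updated.label,
    )


def make_valueset_monitors(
    weights_original: DemographicWeights,
    weights_updated: DemographicWeights,
    cells,
) -> dict:
    """Inline per-draw monitor callables (names ``orig[MO2]``,
    ``upd[MO2]``, ``diff[MO2]``, ...) matching
    :func:`monitor_valuesets` bit for bit."""
    w_o = weights_original.aligned(cells)
    w_u = weights_updated.aligned(cells)
    monitors = {}
    for j, lab in enumerate(DECREMENT_LABELS):
        d = dimension_of_label(lab)

        def f_orig(p: ModelParams, j=j, d=d):
            return float(p.beta[j] * (p.phi[d] * w_o).sum(axis=-1))

        def f_upd(p: ModelParams, j=j, d=d):
            return float(p.beta[j] * (p.phi[d] * w_u).sum(axis=-1))

        def f_diff(p: ModelParams, j=j, d=d):
            return f_upd(p, j, d) - f_orig(p, j, d)

        monitors[f"orig[{lab}]"] = f_orig
        monitors[f"upd[{lab}]"] = f_upd
        monitors[f"diff[{lab}]"] = f_diff
    return monitors


def summarize(vs_draws: ValueSetDraws, level: float = 0.95) -> pd.DataFrame:
    """Posterior mean and equal-tailed credible interval per decrement.

    Percentiles use linear interpolation between order statistics
    (``numpy`` default), fixed here for reproducibility.  The
    ``diff_significant`` flag marks difference intervals excluding 0.
    """
    n = vs_draws.n_draws_total
    if n < 100:
        raise ValueError(f"need at least 100 draws to summarize, got {n}")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    alpha = (1.0 - level) / 2.0
    rows = []
    for j, lab in enumerate(vs_draws.labels):
        row = {"label": lab}
        for stem, arr in (
            ("original", vs_draws.original),
            ("updated", vs_draws.updated),
            ("diff", vs_draws.diff),
        ):
            flat = arr[:, :, j].reshape(-1)
            lo, hi = np.quantile(flat, [alpha, 1.0 - alpha], method="linear")
            row[f"{stem}_mean"] = float(flat.mean())
            row[f"{stem}_lo"] = float(lo)
            row[f"{stem}_hi"] = float(hi)
        row["diff_significant"] = bool(row["diff_lo"] > 0 or row["diff_hi"] < 0)
        rows.append(row)
    cols = list(VALUESET_COLUMNS) + ["diff_significant"]
    return pd.DataFrame(rows)[cols]


def valueset_from_params(params: ModelParams, weights: DemographicWeights):
    """One draw's value set: (intercept, {label: weighted decrement})."""
    w = weights.aligned(params.cells)
    decrements = {}
    for j, lab in enumerate(DECREMENT_LABELS):
        d = dimension_of_label(lab)
        decrements[lab] = weighted_decrement(params.beta[j], params.phi[d], w)
    return float(params.beta0), decrements


def predict_state_value(state, intercept: float, decrements) -> float:
    """Predicted value of a health state from a value set: intercept
    plus the decrements selected by the state's indicator vector."""
    x = encode_state(state)
    value = float(intercept)
    for j, lab in enumerate(DECREMENT_LABELS):
        if x[j]:
            value += float(decrements[lab])
    return value


def predict_from_summary(
    summary: pd.DataFrame, state, intercept: float, which: str = "original"
) -> float:
    """Predict a state's value from a summary table's posterior-mean
    decrements (``which`` in {"original", "updated"})."""
    if which not in ("original", "updated"):
        raise ValueError("which must be 'original' or 'updated'")
    decs = dict(zip(summary["label"], summary[f"{which}_mean"]))
    return predict_state_value(state, intercept, decs)
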