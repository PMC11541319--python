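"""Respondent-level quality-control filters applied before modelling.

Two sequential exclusion rules:

1. respondents who completed fewer than 10 TTO tasks are dropped;
2. of the remainder, respondents whose TTO values *increase* with the
   misery index of the valued states (OLS slope > 0) are dropped --
   valuing strictly worse health higher is taken as nonsense responding.

A respondent hit by both rules is counted under the first only, so the
report's counts add up the way a sequential "first..., second..."
accounting does.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import ValuationDataset

#: slopes within this tolerance of zero are treated as exactly zero
SLOPE_TOL = 1e-12


@dataclass
class FilterReport:
    """Audit trail of the two-stage respondent exclusion."""

    n_input: int
    n_excluded_min_obs: int
    n_excluded_positive_slope: int
    n_retained: int
    records: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_retained != (
            self.n_input - self.n_excluded_min_obs - self.n_excluded_positive_slope
        ):
            raise ValueError("filter report counts are inconsistent")

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {
                "n_input": self.n_input,
                "n_excluded_min_obs": self.n_excluded_min_obs,
                "n_excluded_positive_slope": self.n_excluded_positive_slope,
                "n_retained": self.n_retained,
                "records": self.records,
            },
            indent=2,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload


def filter_min_observations(
    dataset: ValuationDataset, min_obs: int = 10
) -> tuple[ValuationDataset, list[str]]:
    """Drop respondents with fewer than ``min_obs`` observations.

    "Fewer than 10" is strict: 9 tasks excludes, 10 keeps.
    """
    kept, excluded = [], []
    for r in dataset.respondents:
        (kept if r.n_observations >= min_obs else excluded).append(r)
    return (
        ValuationDataset(kept, dataset.design_dialect, dataset.provenance),
        [r.respondent_id for r in excluded],
    )


def respondent_slope(values, misery) -> float:
    """OLS slope of TTO value on misery index for one respondent.

    Returns ``nan`` when all misery values coincide (slope undefined).
    """
    y = np.asarray(values, dtype=float)
    x = np.asarray(misery, dtype=float)
    if y.shape != x.shape or y.ndim != 1 or len(y) < 2:
        raise ValueError("need >= 2 paired (value, misery) observations")
    xc = x - x.mean()
    sxx = float(xc @ xc)
    if sxx == 0.0:
        return float("nan")
    return float(xc @ (y - y.mean()) / sxx)


def filter_positive_slope(
    dataset: ValuationDataset,
) -> tuple[ValuationDataset, list[str]]:
    """Drop respondents whose value-vs-misery OLS slope is positive.

    Zero slope (within :data:`SLOPE_TOL`) is not positive and is
    retained.  An undefined slope (all tasks at one misery level --
    impossible under the real designs) retains the respondent with a
    warning: there is no evidence of nonsense responding.
    """
    kept, excluded = [], []
    for r in dataset.respondents:
        slope = respondent_slope(r.values(), r.miseries())
        if np.isnan(slope):
            warnings.warn(
                f"respondent {r.respondent_id}: slope undefined "
                "(single misery level); retained",
                stacklevel=2,
            )
            kept.append(r)
        elif slope > SLOPE_TOL:
            excluded.append(r)
        else:
            kept.append(r)
    return (
        ValuationDataset(kept, dataset.design_dialect, dataset.provenance),
        [r.respondent_id for r in excluded],
    )


def run_qc(
    dataset: ValuationDataset, min_obs: int = 10
) -> tuple[ValuationDataset, FilterReport]:
    """Apply both exclusion rules in order and return an audit report."""
    n_input = dataset.n_respondents
    after_min, low = filter_min_observations(dataset, min_obs)
    after_slope, sloped = filter_positive_slope(after_min)
    records = [{"respondent_id": rid, "rule": "min_observations"} for rid in low]
    slope_by_id = {
        r.respondent_id: respondent_slope(r.values(), r.miseries())
        for r in after_min.respondents
        if r.respondent_id in set(sloped)
    }
    records += [
        {"respondent_id": rid, "rule": "positive_slope", "slope": slope_by_id[rid]}
        for rid in sloped
    ]
    report = FilterReport(
        n_input=n_input,
        n_excluded_min_obs=len(low),
        n_excluded_positive_slope=len(sloped),
        n_retained=after_slope.n_respondents,
        records=records,
    )
    return after_slope, report
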