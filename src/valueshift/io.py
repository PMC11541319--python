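"""Readers and writers for valuation tables, demographic weights,
posterior draws and value-set summaries.

The canonical long format for TTO data is a delimited text file with a
header and the columns ``respondent_id, sex, age, state, value`` (one
row per respondent x task).  Files with other headers are adapted via a
column-mapping dict or YAML file; real archive layouts are never
hard-coded.  Demographic weight tables carry one row per sex x
age-group cell and are accepted either as proportions (summing to ~1)
or percentages (summing to ~100), auto-detected and re-normalized so
that rounding in printed tables cannot poison downstream sums.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .core import (
    AGE_GROUPS,
    DemographicCell,
    HealthState,
    RespondentRecord,
    TTOObservation,
    assign_age_group,
    standard_cells,
)

CANONICAL_COLUMNS = ("respondent_id", "sex", "age", "state", "value")

#: packaged national compositions (Table-style percent files) and the
#: three survey-sample compositions used by the synthetic generator
REFERENCE_WEIGHTS = {
    "UK-1997": "uk_1997.csv",
    "UK-2022": "uk_2022.csv",
    "JPN-1998": "jpn_1998.csv",
    "JPN-2022": "jpn_2022.csv",
    "US-2002": "us_2002.csv",
    "US-2022": "us_2022.csv",
    "UK-sample": "uk_sample.csv",
    "JPN-sample": "jpn_sample.csv",
    "US-sample": "us_sample.csv",
}

_SEX_ALIASES = {
    "male": "male", "m": "male", "1": "male",
    "female": "female", "f": "female", "2": "female",
}


@dataclass
class DemographicWeights:
    """Population shares over demographic cells at a named time point."""

    label: str
    weights: dict[DemographicCell, float]

    def __post_init__(self) -> None:
        total = float(sum(self.weights.values()))
        if not np.isclose(total, 1.0, atol=1e-6):
            raise ValueError(
                f"weights {self.label!r} sum to {total}, expected 1 within 1e-6"
            )
        for cell, w in self.weights.items():
            if not 0.0 <= w <= 1.0:
                raise ValueError(f"weight {w} for cell {cell.label} outside [0, 1]")

    def aligned(self, cells) -> np.ndarray:
        """Shares as a vector aligned to ``cells``; every cell must be present."""
        missing = [c for c in cells if c not in self.weights]
        if missing:
            raise ValueError(
                f"weights {self.label!r} missing cells: "
                + ", ".join(c.label for c in missing)
            )
        return np.array([self.weights[c] for c in cells], dtype=float)


@dataclass
class ValuationDataset:
    """A TTO valuation study in memory: respondents with their tasks."""

    respondents: list[RespondentRecord]
    design_dialect: str = "unknown"
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [r.respondent_id for r in self.respondents]
        if len(ids) != len(set(ids)):
            raise ValueError("respondent ids are not unique")

    @property
    def n_respondents(self) -> int:
        return len(self.respondents)

    @property
    def n_observations(self) -> int:
        return sum(r.n_observations for r in self.respondents)

    def iter_observations(self):
        for r in self.respondents:
            for obs in r.observations:
                yield r, obs

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (r.respondent_id, r.cell.sex,
             r.age_years if r.age_years is not None else r.cell.age_group,
             obs.state.code, obs.value)
            for r, obs in self.iter_observations()
        ]
        return pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS))


def _normalize_age_token(tok: str) -> str:
    return tok.replace("–", "-").replace("—", "-").strip()


def _parse_sex(raw, line_no: int) -> str:
    key = str(raw).strip().lower()
    if key not in _SEX_ALIASES:
        raise ValueError(f"line {line_no}: unparseable sex value {raw!r}")
    return _SEX_ALIASES[key]


def _parse_age(raw, line_no: int) -> tuple[str, int | None]:
    """Return (age_group, age_years-or-None); accepts years or band strings."""
    tok = _normalize_age_token(str(raw))
    if tok in AGE_GROUPS or tok in {_normalize_age_token(a) for a in AGE_GROUPS}:
        return tok, None
    try:
        years = int(float(tok))
    except ValueError:
        raise ValueError(f"line {line_no}: unparseable age value {raw!r}") from None
    return assign_age_group(years), years


def _load_column_map(column_map) -> dict[str, str]:
    if column_map is None:
        return {c: c for c in CANONICAL_COLUMNS}
    if isinstance(column_map, (str, Path)):
        with open(column_map) as fh:
            column_map = yaml.safe_load(fh)
        if isinstance(column_map, dict) and "columns" in column_map:
            column_map = column_map["columns"]
    if not isinstance(column_map, Mapping):
        raise ValueError("column map must be a mapping or a YAML file containing one")
    mapping = {c: c for c in CANONICAL_COLUMNS}
    mapping.update({str(k): str(v) for k, v in column_map.items()})
    return mapping


def read_tto_table(
    path,
    column_map=None,
    sep: str | None = None,
    max_value: float | None = 1.0,
    dialect: str = "unknown",
) -> ValuationDataset:
    """Read a long-format TTO table into a :class:`ValuationDataset`.

    Parameters
    ----------
    column_map
        Mapping from canonical column names to the file's header names
        (dict, or path to a YAML file with such a mapping, optionally
        under a ``columns:`` key).
    sep
        Field separator; by default inferred from the extension
        (``.tsv`` -> tab, otherwise comma).
    max_value
        Upper bound enforced on TTO values (real TTO data cannot exceed
        full health = 1).  Pass ``None`` to accept model-scale synthetic
        values above 1.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    mapping = _load_column_map(column_map)
    missing = [canon for canon, actual in mapping.items() if actual not in df.columns]
    if missing:
        raise ValueError(
            f"{path.name}: missing mandatory column(s) "
            + ", ".join(f"{m!r} (mapped to {mapping[m]!r})" for m in missing)
        )
    df = df.rename(columns={v: k for k, v in mapping.items()})

    errors: list[str] = []
    respondents: dict[str, RespondentRecord] = {}
    for idx, row in enumerate(df.itertuples(index=False)):
        line_no = idx + 2  # header is line 1
        try:
            rid = str(getattr(row, "respondent_id")).strip()
            sex = _parse_sex(getattr(row, "sex"), line_no)
            band, years = _parse_age(getattr(row, "age"), line_no)
            state = HealthState(str(getattr(row, "state")).strip())
            value = float(getattr(row, "value"))
            if max_value is not None and value > max_value + 1e-9:
                raise ValueError(
                    f"line {line_no}: TTO value {value} exceeds maximum {max_value}"
                )
            obs = TTOObservation(rid, state, value)
        except ValueError as exc:
            msg = str(exc)
            errors.append(msg if msg.startswith("line ") else f"line {line_no}: {msg}")
            continue
        rec = respondents.get(rid)
        if rec is None:
            rec = RespondentRecord(rid, DemographicCell(sex, band), [], years)
            respondents[rid] = rec
        rec.observations.append(obs)
    if errors:
        raise ValueError(
            f"{path.name}: {len(errors)} malformed row(s):\n" + "\n".join(errors[:20])
        )
    return ValuationDataset(
        list(respondents.values()), design_dialect=dialect, provenance=str(path)
    )


def write_tto_table(dataset: ValuationDataset, path) -> None:
    """Serialize a dataset back to the canonical long CSV format."""
    dataset.to_frame().to_csv(path, index=False, float_format="%.17g")


def read_weights(path, label: str | None = None, scale: str = "auto") -> DemographicWeights:
    """Read a demographic-weight table (columns ``sex, age_group, share``).

    ``scale`` is ``"auto"`` (detect percent vs proportion from the
    total), ``"percent"`` or ``"proportion"``.  Shares are re-normalized
    to sum exactly to 1.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep)
    for col in ("sex", "age_group", "share"):
        if col not in df.columns:
            raise ValueError(f"{path.name}: missing mandatory column {col!r}")
    total = float(df["share"].sum())
    if scale == "auto":
        if abs(total - 1.0) <= 0.01:
            divisor = total
        elif abs(total - 100.0) <= 1.0:
            divisor = total
        else:
            raise ValueError(
                f"{path.name}: shares sum to {total}, neither ~1 nor ~100 within 1%"
            )
    elif scale == "percent":
        divisor = total
    elif scale == "proportion":
        divisor = total
    else:
        raise ValueError(f"unknown scale {scale!r}")
    weights = {}
    for _, row in df.iterrows():
        cell = DemographicCell(
            _parse_sex(row["sex"], 0), _normalize_age_token(str(row["age_group"]))
        )
        if cell in weights:
            raise ValueError(f"{path.name}: duplicate cell {cell.label}")
        weights[cell] = float(row["share"]) / divisor
    return DemographicWeights(label or path.stem, weights)


def write_weights(weights: DemographicWeights, path) -> None:
    rows = [(c.sex, c.age_group, w) for c, w in sorted(weights.weights.items())]
    pd.DataFrame(rows, columns=["sex", "age_group", "share"]).to_csv(
        path, index=False, float_format="%.17g"
    )


def load_reference_weights(name: str) -> DemographicWeights:
    """Load one of the packaged national/sample compositions by label."""
    if name not in REFERENCE_WEIGHTS:
        raise ValueError(
            f"unknown reference weights {name!r}; available: "
            + ", ".join(sorted(REFERENCE_WEIGHTS))
        )
    res = importlib.resources.files("valueshift.data") / REFERENCE_WEIGHTS[name]
    with importlib.resources.as_file(res) as p:
        return read_weights(p, label=name)


# ---------------------------------------------------------------------------
# posterior draws: flat table (chain, draw, parameter, value)
# ---------------------------------------------------------------------------

VALUESET_COLUMNS = (
    "label",
    "original_mean", "original_lo", "original_hi",
    "updated_mean", "updated_lo", "updated_hi",
    "diff_mean", "diff_lo", "diff_hi",
)


def write_draws_table(df: pd.DataFrame, path) -> None:
    """Write a flat draws table with columns chain, draw, parameter, value."""
    expected = {"chain", "draw", "parameter", "value"}
    if not expected.issubset(df.columns):
        raise ValueError(f"draws table needs columns {sorted(expected)}")
    df.to_csv(path, index=False, float_format="%.17g")


def read_draws_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    expected = {"chain", "draw", "parameter", "value"}
    if not expected.issubset(df.columns):
        raise ValueError(f"{Path(path).name}: not a draws table")
    return df


def write_valueset(summary: pd.DataFrame, path) -> None:
    """Write a value-set summary table (original / updated / difference).

    Expects one row per decrement label with posterior mean and 95%
    credible bounds for the original weighting, the updated weighting
    and their difference.  Rejects inverted intervals.
    """
    missing = [c for c in VALUESET_COLUMNS if c not in summary.columns]
    if missing:
        raise ValueError(f"value-set summary missing columns: {missing}")
    for stem in ("original", "updated", "diff"):
        lo, hi = summary[f"{stem}_lo"], summary[f"{stem}_hi"]
        bad = summary.loc[np.asarray(lo) > np.asarray(hi), "label"]
        if len(bad):
            raise ValueError(
                f"inverted credible interval ({stem}) for: {', '.join(bad)}"
            )
    cols = list(VALUESET_COLUMNS) + [
        c for c in summary.columns if c not in VALUESET_COLUMNS
    ]
    summary[cols].to_csv(path, index=False, float_format="%.17g")


def read_valueset(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in VALUESET_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{Path(path).name}: missing columns {missing}")
    return df
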