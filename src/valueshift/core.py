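"""Domain types for EQ-5D-3L health-state valuation.

The EQ-5D-3L descriptive system has five dimensions -- mobility (MO),
self-care (SC), usual activities (UA), pain/discomfort (PD) and
anxiety/depression (AD) -- each at three levels, giving 243 health
states written as five-digit codes such as ``"21321"``.  Digit order is
the standard EQ-5D convention MO, SC, UA, PD, AD.

Time trade-off (TTO) observations carry a value on ``[-1, 1]`` in real
survey data; the latent valuation model is unbounded above, so
synthetic observations may exceed 1 (file readers reject such values
for real data by default, see :mod:`valueshift.io`).  Values of exactly
-1 are the censoring mass point of the Tobit model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DIMENSIONS: tuple[str, ...] = ("MO", "SC", "UA", "PD", "AD")
DECREMENT_LABELS: tuple[str, ...] = (
    "MO2", "MO3", "SC2", "SC3", "UA2", "UA3", "PD2", "PD3", "AD2", "AD3",
)
AGE_GROUPS: tuple[str, ...] = ("18-34", "35-54", "55-74", "75+")
SEXES: tuple[str, ...] = ("male", "female")

#: tolerance for identifying the censoring mass point at -1
CENSOR_TOL = 1e-9


def _validate_code(code: str) -> str:
    if not isinstance(code, str) or len(code) != 5 or any(c not in "123" for c in code):
        raise ValueError(
            f"invalid EQ-5D-3L state code {code!r}: expected 5 characters, each in 1-3"
        )
    return code


@dataclass(frozen=True)
class HealthState:
    """One EQ-5D-3L profile, e.g. ``HealthState("21321")``."""

    code: str

    def __post_init__(self) -> None:
        _validate_code(self.code)

    @property
    def levels(self) -> tuple[int, ...]:
        return tuple(int(c) for c in self.code)

    def dummies(self) -> np.ndarray:
        return encode_state(self)

    def misery(self) -> int:
        return misery_index(self)


def _as_state(state: HealthState | str) -> HealthState:
    return state if isinstance(state, HealthState) else HealthState(state)


def encode_state(state: HealthState | str) -> np.ndarray:
    """Indicator vector of length 10 in decrement order MO2, MO3, ..., AD3.

    Entry ``2d`` is 1 iff dimension ``d`` is at level 2, entry ``2d+1``
    is 1 iff it is at level 3; level 1 contributes nothing.
    """
    state = _as_state(state)
    out = np.zeros(10, dtype=np.int8)
    for d, lev in enumerate(state.levels):
        if lev == 2:
            out[2 * d] = 1
        elif lev == 3:
            out[2 * d + 1] = 1
    return out


def misery_index(state: HealthState | str) -> int:
    """Sum of the five levels; a crude severity score in [5, 15]."""
    return sum(_as_state(state).levels)


def assign_age_group(age_years: int) -> str:
    """Recode an adult age in years into the four analysis bands."""
    age = int(age_years)
    if age < 18:
        raise ValueError(f"age {age} below 18: adult valuation samples only")
    if age <= 34:
        return "18-34"
    if age <= 54:
        return "35-54"
    if age <= 74:
        return "55-74"
    return "75+"


@dataclass(frozen=True, order=True)
class DemographicCell:
    """A sex x age-group population cell, the unit of preference scaling."""

    sex: str
    age_group: str

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"unknown sex {self.sex!r}: expected one of {SEXES}")
        if self.age_group not in AGE_GROUPS:
            raise ValueError(
                f"unknown age group {self.age_group!r}: expected one of {AGE_GROUPS}"
            )

    @property
    def label(self) -> str:
        return f"{self.sex} {self.age_group}"


def standard_cells() -> tuple[DemographicCell, ...]:
    """The default G=8 cells, males first, then females, youngest to oldest."""
    return tuple(DemographicCell(s, a) for s in SEXES for a in AGE_GROUPS)


@dataclass(frozen=True)
class TTOObservation:
    """One elicited TTO value for one health state.

    ``censored`` marks the Tobit mass point: an observed value of
    exactly -1 (within :data:`CENSOR_TOL`) is read as a censored
    worse-than-dead response.
    """

    respondent_id: str
    state: HealthState
    value: float
    censored: bool = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        v = float(self.value)
        if v < -1.0 - CENSOR_TOL:
            raise ValueError(
                f"TTO value {v} below the censoring bound -1 "
                f"(respondent {self.respondent_id}, state {self.state.code})"
            )
        cens = abs(v - (-1.0)) <= CENSOR_TOL
        object.__setattr__(self, "value", -1.0 if cens else v)
        object.__setattr__(self, "censored", cens)


@dataclass
class RespondentRecord:
    """A respondent's demographic cell and completed TTO tasks."""

    respondent_id: str
    cell: DemographicCell
    observations: list[TTOObservation] = field(default_factory=list)
    age_years: int | None = None

    def __post_init__(self) -> None:
        if self.age_years is not None:
            band = assign_age_group(self.age_years)
            if band != self.cell.age_group:
                raise ValueError(
                    f"respondent {self.respondent_id}: age {self.age_years} "
                    f"implies band {band!r} but cell says {self.cell.age_group!r}"
                )
        for obs in self.observations:
            if obs.respondent_id != self.respondent_id:
                raise ValueError(
                    f"observation of respondent {obs.respondent_id} attached "
                    f"to record {self.respondent_id}"
                )

    @property
    def n_observations(self) -> int:
        return len(self.observations)

    def values(self) -> np.ndarray:
        return np.array([o.value for o in self.observations], dtype=float)

    def miseries(self) -> np.ndarray:
        return np.array([o.state.misery() for o in self.observations], dtype=float)


def all_states() -> list[HealthState]:
    """All 243 EQ-5D-3L states in lexicographic code order."""
    return [
        HealthState(f"{a}{b}{c}{d}{e}")
        for a in "123" for b in "123" for c in "123" for d in "123" for e in "123"
    ]
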