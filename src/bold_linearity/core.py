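"""Core domain containers shared by every stage of the analysis.

The analysis operates on per-voxel BOLD time series sampled at a fixed
repetition time (TR).  Three containers carry the data through the
pipeline:

``TimeCourse``
    a sampled BOLD series (raw scanner units or percent signal change),
``Paradigm``
    the trial schedule of a run (localizer block design or event-related
    contrast-adaptation design),
``MeasuredResponse``
    the 25-sample trial-averaged percent-signal response of one voxel to
    one condition, the object the linearity statistics are computed on.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "Condition",
    "Event",
    "Paradigm",
    "TimeCourse",
    "MeasuredResponse",
    "CONDITIONS",
    "RESPONSE_TYPES",
    "TEST_DURATIONS_S",
]

RESPONSE_TYPES = ("increment", "decrement")
TEST_DURATIONS_S = (1.0, 3.0, 6.0)


@dataclass(frozen=True, order=True)
class Condition:
    """A test-stimulus condition: contrast step direction x duration.

    ``increment`` voxels see the adapted contrast raised (25% -> 100%),
    ``decrement`` voxels see it lowered (25% -> 6.25%); the test stimulus
    lasts 1, 3 or 6 s.
    """

    response_type: Literal["increment", "decrement"]
    test_duration_s: float

    def __post_init__(self) -> None:
        if self.response_type not in RESPONSE_TYPES:
            raise ValueError(f"unknown response_type {self.response_type!r}")
        if self.test_duration_s <= 0:
            raise ValueError("test_duration_s must be positive")

    @property
    def label(self) -> str:
        d = self.test_duration_s
        dur = int(d) if float(d).is_integer() else d
        return f"{self.response_type}_{dur}s"


#: The six conditions of the adaptation experiment (2 response types x 3 durations).
CONDITIONS: tuple[Condition, ...] = tuple(
    Condition(rt, d) for rt in RESPONSE_TYPES for d in TEST_DURATIONS_S
)


@dataclass(frozen=True)
class Event:
    """One stimulus presentation: onset and duration in seconds.

    ``condition`` is a :class:`Condition` for adaptation test events, or the
    string labels ``"localizer"`` / ``"adaptation"`` for block / pedestal
    stimuli.
    """

    onset_s: float
    duration_s: float
    condition: Condition | str

    @property
    def offset_s(self) -> float:
        return self.onset_s + self.duration_s


@dataclass(frozen=True)
class Paradigm:
    """Trial schedule of one run.

    For ``kind="adaptation"`` the events list holds the 24 test events; the
    60-s adaptation pedestal that starts at ``adaptation_onset_s`` and the
    per-trial 30-s adaptation segments are implicit in the design (the
    adaptation stimulus is on screen from ``adaptation_onset_s`` to the end
    of the run except while a test stimulus replaces it).
    """

    events: tuple[Event, ...]
    run_length_s: float
    tr_s: float
    kind: Literal["localizer", "adaptation"]
    adaptation_onset_s: float | None = None

    def __post_init__(self) -> None:
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")
        last_end = -np.inf
        prev_onset = -np.inf
        for ev in self.events:
            ratio = ev.onset_s / self.tr_s
            if ev.onset_s < 0 or abs(ratio - round(ratio)) > 1e-9:
                raise ValueError(
                    f"event onset {ev.onset_s} is not a non-negative multiple of TR"
                )
            if ev.onset_s <= prev_onset:
                raise ValueError("event onsets must be strictly increasing")
            if ev.onset_s < last_end:
                raise ValueError("events overlap")
            if ev.offset_s > self.run_length_s + 1e-9:
                raise ValueError("event extends past run end")
            prev_onset = ev.onset_s
            last_end = ev.offset_s

    @property
    def n_volumes(self) -> int:
        return int(round(self.run_length_s / self.tr_s))

    def test_events(self) -> tuple[Event, ...]:
        """Events whose condition is a :class:`Condition` (adaptation tests)."""
        return tuple(ev for ev in self.events if isinstance(ev.condition, Condition))

    def events_for(self, condition: Condition) -> tuple[Event, ...]:
        return tuple(ev for ev in self.events if ev.condition == condition)


@dataclass(frozen=True)
class TimeCourse:
    """A sampled BOLD series.

    ``t0_s`` is the acquisition time of the first retained sample, so that a
    course whose leading volumes were discarded still indexes paradigm
    onsets correctly.
    """

    values: np.ndarray
    tr_s: float
    unit: Literal["raw", "percent"] = "raw"
    origin: str = ""
    t0_s: float = 0.0

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or values.size < 2:
            raise ValueError("values must be a 1-D series of length >= 2")
        if not np.all(np.isfinite(values)):
            raise ValueError("values must be finite")
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def times_s(self) -> np.ndarray:
        return self.t0_s + self.tr_s * np.arange(len(self.values))

    def with_values(self, values: np.ndarray, *, unit: str | None = None,
                    origin: str | None = None, t0_s: float | None = None) -> "TimeCourse":
        return TimeCourse(
            values=np.asarray(values, dtype=float),
            tr_s=self.tr_s,
            unit=self.unit if unit is None else unit,  # type: ignore[arg-type]
            origin=self.origin if origin is None else origin,
            t0_s=self.t0_s if t0_s is None else t0_s,
        )


@dataclass(frozen=True)
class MeasuredResponse:
    """Trial-averaged percent-signal response of one voxel to one condition.

    Always 25 samples at TR = 1 s: trials are unified to the first 25
    volumes after test-stimulus onset so that responses to different
    durations are comparable.
    """

    values: np.ndarray
    voxel_id: int
    condition: Condition
    n_trials_averaged: int
    tr_s: float = 1.0

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.shape != (25,):
            raise ValueError(f"measured response must have 25 samples, got {values.shape}")
        if not np.all(np.isfinite(values)):
            raise ValueError("values must be finite")
        if self.n_trials_averaged < 1:
            raise ValueError("n_trials_averaged must be >= 1")
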