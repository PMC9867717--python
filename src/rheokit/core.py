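"""Shared conventions, error types, and the stimulus schedule.

Coordinate frame
----------------
The arena is a ``width x height`` mm rectangle with the origin at the
front-left corner.  ``+y`` points downstream (the direction the water
travels), so the upstream unit vector is ``(0, -1)``.  Heading angles are
measured relative to upstream: 0 deg = facing directly into the oncoming
flow, positive = right of upstream, negative = left, canonicalized to
``(-180, 180]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: keypoints tracked on each larva, in canonical order
KEYPOINTS = (
    "left_eye",
    "right_eye",
    "swim_bladder",
    "tail1",
    "tail2",
    "tail3",
    "tail4",
)

TREATMENTS = ("control", "cuso4", "neomycin", "custom")

EPOCH_NAMES = ("no_flow", "initial_flow", "final_flow")

#: default analysis bin width, seconds (lowest common bin of 60 and 200 fps data)
DEFAULT_BIN_S = 0.1

#: flow speed used throughout the study, mm / s
DEFAULT_FLOW_SPEED = 9.74


class RheokitError(Exception):
    """Base class for all package errors."""


class FormatError(RheokitError):
    """Input file does not match any accepted pose-table dialect."""


class DataError(RheokitError):
    """Input data are structurally valid but violate a data contract."""


class ParameterError(RheokitError, ValueError):
    """A user-supplied parameter is out of range or inconsistent."""


class InsufficientDataError(DataError):
    """Not enough valid samples to compute the requested quantity."""


class ScheduleError(RheokitError):
    """Stimulus schedule does not cover or align with the track."""


class ConfigError(RheokitError):
    """Run configuration is invalid."""


@dataclass(frozen=True)
class Epoch:
    name: str
    start: float  # s
    end: float    # s

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class StimulusSchedule:
    """Trial stimulus structure: contiguous epochs plus the flow stimulus.

    The default reproduces the assay design: 10 s no flow, then 20 s of
    constant flow (split into initial and final halves) at 9.74 mm/s
    directed downstream (+y).
    """

    epochs: tuple[Epoch, ...] = (
        Epoch("no_flow", 0.0, 10.0),
        Epoch("initial_flow", 10.0, 20.0),
        Epoch("final_flow", 20.0, 30.0),
    )
    flow_speed: float = DEFAULT_FLOW_SPEED
    flow_direction: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        if self.flow_speed < 0:
            raise ParameterError("flow_speed must be >= 0")
        d = np.hypot(*self.flow_direction)
        if not np.isclose(d, 1.0):
            raise ParameterError("flow_direction must be a unit vector")
        prev_end = None
        for ep in self.epochs:
            if ep.end <= ep.start:
                raise ScheduleError(f"epoch {ep.name} has non-positive duration")
            if prev_end is not None and not np.isclose(ep.start, prev_end):
                raise ScheduleError("epochs must be contiguous and non-overlapping")
            prev_end = ep.end

    @property
    def start(self) -> float:
        return self.epochs[0].start

    @property
    def end(self) -> float:
        return self.epochs[-1].end

    @property
    def duration(self) -> float:
        return self.end - self.start

    @property
    def upstream(self) -> np.ndarray:
        return -np.asarray(self.flow_direction, dtype=float)

    def flow_epochs(self) -> tuple[Epoch, ...]:
        return tuple(ep for ep in self.epochs if ep.name != "no_flow")

    @property
    def flow_onset(self) -> float:
        """Start of the first flow epoch; None-safe only for flow schedules."""
        flow = self.flow_epochs()
        if not flow:
            raise ScheduleError("schedule has no flow epoch")
        return flow[0].start

    def flow_on(self, t: np.ndarray) -> np.ndarray:
        """Boolean mask: is the flow stimulus on at time(s) t."""
        t = np.asarray(t, dtype=float)
        on = np.zeros(t.shape, dtype=bool)
        for ep in self.flow_epochs():
            on |= (t >= ep.start) & (t < ep.end)
        return on

    def epoch_of(self, t: np.ndarray) -> np.ndarray:
        """Epoch name for each time; empty string outside the schedule."""
        t = np.asarray(t, dtype=float)
        out = np.full(t.shape, "", dtype=object)
        for ep in self.epochs:
            sel = (t >= ep.start) & (t < ep.end)
            out[sel] = ep.name
        # the final instant belongs to the last epoch
        out[np.isclose(t, self.end)] = self.epochs[-1].name
        return out


def wrap_degrees(angle):
    """Wrap angle(s) to the canonical (-180, 180] interval (-180 -> +180)."""
    a = np.asarray(angle, dtype=float)
    wrapped = -np.mod(180.0 - a, 360.0) + 180.0
    return wrapped if wrapped.ndim else float(wrapped)


def signed_angle(u: np.ndarray, v: np.ndarray) -> float:
    """Signed angle (degrees) from vector u to vector v, CCW-positive in the
    arena frame (+x right, +y downstream), canonicalized to (-180, 180]."""
    cross = u[0] * v[1] - u[1] * v[0]
    dot = u[0] * v[0] + u[1] * v[1]
    return wrap_degrees(np.degrees(np.arctan2(cross, dot)))
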