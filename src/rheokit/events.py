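"""Positive-rheotaxis event classification and event-level metrics.

A positive rheotaxis event is a maximal run of consecutive valid 100-ms
bins in which the fish (i) faces the oncoming flow within 0 +/- 45 deg,
(ii) beats its tail, and (iii) translates upstream — lasting at least
100 ms.  The tail and translation requirements separate active swimming
into the flow from passive downstream drift at a compliant body angle.
Under no flow the same angular band is scored against the nominal flow
axis; by default orientation alone defines a no-flow "event" (the
standardization condition), with the full rule available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .circstats import circular_mean
from .core import ParameterError, StimulusSchedule, wrap_degrees
from .kinematics import KinematicSeries


@dataclass
class RheotaxisEvent:
    trial_id: str
    start: float       # s
    end: float         # s
    mean_heading: float  # deg, circular mean over event bins
    distance: float    # mm traveled during the event
    epochs: tuple[str, ...]

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class EventSummary:
    """Per trial x epoch event metrics (events split at epoch boundaries)."""

    trial_id: str
    per_epoch: pd.DataFrame  # epoch, n_events, mean_duration, total_distance
    latency: float           # s from flow onset to first in-flow event start


def classify_events(
    series: KinematicSeries,
    angle_band: float = 45.0,
    min_bout: float = 0.1,
    tail_amp_min: float = 0.3,
    min_forward_translation: float = 0.0,
    no_flow_mode: str = "orientation",
) -> list[RheotaxisEvent]:
    """Classify positive rheotaxis events on a per-bin kinematic series.

    ``no_flow_mode``: "orientation" scores no-flow bins on the angular band
    alone; "full" applies the tail/translation criteria there too.
    A single invalid or missing bin breaks a run; runs shorter than
    ``min_bout`` seconds are discarded.
    """
    if angle_band <= 0 or min_bout <= 0:
        raise ParameterError("angle_band and min_bout must be > 0")
    if no_flow_mode not in ("orientation", "full"):
        raise ParameterError("no_flow_mode must be 'orientation' or 'full'")

    df = series.df
    dt = series.bin_s
    heading = df["heading"].to_numpy(dtype=float)
    tail = df["tail_amplitude"].to_numpy(dtype=float)
    upstream = df["upstream_mm"].to_numpy(dtype=float)
    valid = df["valid"].to_numpy(dtype=bool) & np.isfinite(heading)
    in_band = np.abs(heading) <= angle_band
    active = (tail >= tail_amp_min) & (upstream > min_forward_translation)
    t_mid = df["bin_start"].to_numpy(dtype=float) + dt / 2.0
    flow_on = series.schedule.flow_on(t_mid)

    crit = valid & in_band & np.where(
        flow_on | (no_flow_mode == "full"), active, True
    )

    events: list[RheotaxisEvent] = []
    starts = df["bin_start"].to_numpy(dtype=float)
    epochs = df["epoch"].to_numpy()
    i = 0
    n = len(crit)
    while i < n:
        if not crit[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and crit[j + 1]:
            j += 1
        n_bins = j - i + 1
        if n_bins * dt >= min_bout - 1e-12:
            dist = np.nansum(df["distance"].to_numpy(dtype=float)[i : j + 1])
            events.append(
                RheotaxisEvent(
                    trial_id=series.trial_id,
                    start=float(starts[i]),
                    end=float(starts[i] + n_bins * dt),
                    mean_heading=circular_mean(heading[i : j + 1]),
                    distance=float(dist),
                    epochs=tuple(dict.fromkeys(epochs[i : j + 1])),
                )
            )
        i = j + 1
    return events


def split_at_epochs(
    event: RheotaxisEvent, schedule: StimulusSchedule
) -> list[tuple[str, float, float, float]]:
    """Split an event at epoch boundaries.

    Returns ``(epoch, start, end, distance_share)`` pieces whose durations
    sum to the event duration; distance is apportioned by time fraction.
    """
    pieces = []
    for ep in schedule.epochs:
        lo = max(event.start, ep.start)
        hi = min(event.end, ep.end)
        if hi - lo > 1e-9:
            share = event.distance * (hi - lo) / event.duration
            pieces.append((ep.name, lo, hi, share))
    return pieces


def summarize_events(
    events: list[RheotaxisEvent],
    schedule: StimulusSchedule | None = None,
    trial_id: str | None = None,
) -> EventSummary:
    """Per-epoch counts, mean durations, total distances, and latency.

    Events spanning an epoch boundary are split at the boundary and counted
    once in each epoch they touch.  Latency is the delay from flow onset to
    the start of the first event that overlaps a flow epoch; NaN when the
    trial has no such event.
    """
    schedule = schedule or StimulusSchedule()
    if trial_id is None:
        trial_id = events[0].trial_id if events else ""
    rows = {ep.name: {"durations": [], "distance": 0.0} for ep in schedule.epochs}
    first_flow_start = np.nan
    flow_onset = schedule.flow_onset
    for ev in sorted(events, key=lambda e: e.start):
        for name, lo, hi, dist in split_at_epochs(ev, schedule):
            rows[name]["durations"].append(hi - lo)
            rows[name]["distance"] += dist
            if name != "no_flow" and np.isnan(first_flow_start):
                first_flow_start = max(ev.start, flow_onset)
    table = pd.DataFrame(
        {
            "epoch": list(rows),
            "n_events": [len(r["durations"]) for r in rows.values()],
            "mean_duration": [
                float(np.mean(r["durations"])) if r["durations"] else np.nan
                for r in rows.values()
            ],
            "total_distance": [r["distance"] for r in rows.values()],
        }
    )
    latency = float(first_flow_start - flow_onset) if np.isfinite(first_flow_start) else np.nan
    return EventSummary(trial_id=trial_id, per_epoch=table, latency=latency)


def responder_curve(
    events_by_trial: dict[str, list[RheotaxisEvent]],
    schedule: StimulusSchedule | None = None,
    bin_s: float = 0.1,
) -> pd.DataFrame:
    """Cumulative proportion of fish that have begun rheotaxis by each bin.

    For every flow bin t, the fraction of trials whose first in-flow event
    starts at or before t.  Monotone non-decreasing by construction.
    """
    schedule = schedule or StimulusSchedule()
    onset = schedule.flow_onset
    end = schedule.end
    t = np.arange(onset, end - bin_s / 2, bin_s)
    firsts = []
    for evs in events_by_trial.values():
        t0 = np.inf
        for ev in evs:
            if ev.end > onset:  # overlaps flow
                t0 = min(t0, max(ev.start, onset))
        firsts.append(t0)
    firsts = np.asarray(firsts)
    prop = (firsts[None, :] <= t[:, None] + bin_s / 2).mean(axis=1)
    return pd.DataFrame({"t": t, "proportion": prop})
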