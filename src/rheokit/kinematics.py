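"""Per-bin linear and angular kinematics, and arena occupancy.

Heading convention: 0 deg = facing directly upstream (into the oncoming
flow), positive = right of upstream, negative = left, wrapped to
(-180, 180].  The body axis runs from the swim bladder to the eye midpoint
(single eye if one is missing).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    InsufficientDataError,
    ParameterError,
    StimulusSchedule,
    signed_angle,
    wrap_degrees,
)
from .track_io import BinnedTrack


@dataclass
class KinematicSeries:
    """Per-bin kinematics of one trial.

    ``df`` columns: bin_start, epoch, valid, heading (deg), distance (mm,
    within-bin path length), velocity (mm/s, speed from successive binned
    positions), acceleration (mm/s^2), tail_amplitude (mm), upstream_mm,
    x, y (mm, swim-bladder bin means).
    """

    trial_id: str
    treatment: str
    session: str
    bin_s: float
    schedule: StimulusSchedule
    arena: tuple[float, float]
    df: pd.DataFrame

    @property
    def n_bins(self) -> int:
        return len(self.df)

    def column(self, name: str) -> np.ndarray:
        return self.df[name].to_numpy(dtype=float)

    def relative(self, name: str) -> np.ndarray:
        """Within-fish mean-centered version of a column (NaN-aware)."""
        v = self.column(name)
        return v - np.nanmean(v)

    def heading_change(self) -> np.ndarray:
        """Absolute circular change in heading between successive bins, deg."""
        h = self.column("heading")
        dh = np.abs(wrap_degrees(np.diff(h)))
        return np.concatenate([[np.nan], dh])


def heading_angle(
    swim_bladder_xy,
    left_eye_xy=None,
    right_eye_xy=None,
    flow_direction=(0.0, 1.0),
) -> float:
    """Signed heading (deg) of the body axis relative to upstream.

    The axis points from the swim bladder to the eye midpoint; if one eye
    is missing the remaining eye is used.  Returns NaN when the swim
    bladder or both eyes are missing.
    """
    sb = np.asarray(swim_bladder_xy, dtype=float)
    eyes = [
        np.asarray(e, dtype=float)
        for e in (left_eye_xy, right_eye_xy)
        if e is not None and np.isfinite(np.asarray(e, dtype=float)).all()
    ]
    if not eyes or not np.isfinite(sb).all():
        return float("nan")
    mid = np.mean(eyes, axis=0)
    axis = mid - sb
    if np.hypot(*axis) == 0:
        return float("nan")
    upstream = -np.asarray(flow_direction, dtype=float)
    return signed_angle(upstream, axis)


def _heading_series(binned: BinnedTrack) -> np.ndarray:
    sb = binned.bin_xy("swim_bladder")
    le = binned.bin_xy("left_eye")
    re = binned.bin_xy("right_eye")
    up = binned.schedule.upstream
    le_ok = np.isfinite(le).all(axis=1)
    re_ok = np.isfinite(re).all(axis=1)
    mid = np.where(
        (le_ok & re_ok)[:, None],
        (le + re) / 2.0,
        np.where(le_ok[:, None], le, re),
    )
    axis = mid - sb
    cross = up[0] * axis[:, 1] - up[1] * axis[:, 0]
    dot = up[0] * axis[:, 0] + up[1] * axis[:, 1]
    with np.errstate(invalid="ignore"):
        h = wrap_degrees(np.degrees(np.arctan2(cross, dot)))
    h = np.where(np.isfinite(axis).all(axis=1), h, np.nan)
    return np.asarray(h, dtype=float)


def linear_series(binned: BinnedTrack) -> KinematicSeries:
    """Derive the per-bin kinematic series from a binned track.

    distance = within-bin swim-bladder path length; velocity = magnitude of
    the first difference of binned position / bin width; acceleration =
    first difference of velocity / bin width.  Differences across a missing
    bin are missing.
    """
    sb = binned.bin_xy("swim_bladder")
    valid = np.isfinite(sb).all(axis=1)
    if valid.sum() < 3:
        raise InsufficientDataError("need >= 3 valid bins")
    dt = binned.bin_s
    vel = np.full(binned.n_bins, np.nan)
    vel[1:] = np.hypot(*np.diff(sb, axis=0).T) / dt
    acc = np.full(binned.n_bins, np.nan)
    acc[1:] = np.diff(vel) / dt
    heading = _heading_series(binned)
    df = pd.DataFrame(
        {
            "bin_start": binned.bin_start,
            "epoch": binned.epoch,
            "valid": valid,
            "heading": heading,
            "distance": binned.path_mm,
            "velocity": vel,
            "acceleration": acc,
            "tail_amplitude": binned.tail_amp_mm,
            "upstream_mm": binned.upstream_mm,
            "x": sb[:, 0],
            "y": sb[:, 1],
        }
    )
    return KinematicSeries(
        trial_id=binned.trial_id,
        treatment=binned.treatment,
        session=binned.session,
        bin_s=binned.bin_s,
        schedule=binned.schedule,
        arena=binned.arena,
        df=df,
    )


# ---------------------------------------------------------------------------
# occupancy

ROI_NAMES = ("FRONT", "BACK", "LEFT", "RIGHT", "MIDDLE")


@dataclass
class ArenaOccupancy:
    """Spatial histogram of bin positions plus region-of-interest fractions.

    FRONT/BACK are full-width bands of depth ``margin`` mm at the upstream
    and downstream walls; LEFT/RIGHT are side bands between them; MIDDLE is
    the remainder.  Corner cells belong to FRONT/BACK.
    """

    grid: np.ndarray
    x_edges: np.ndarray
    y_edges: np.ndarray
    roi_fractions: dict
    n: int
    angle_filter: tuple[float, float] | None
    empty: bool = False


def classify_roi(x, y, arena=(30.0, 30.0), margin=5.0) -> np.ndarray:
    """ROI label for each position (FRONT has priority over LEFT/RIGHT)."""
    w, h = arena
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    out = np.full(x.shape, "MIDDLE", dtype=object)
    out[x < margin] = "LEFT"
    out[x > w - margin] = "RIGHT"
    out[y < margin] = "FRONT"
    out[y > h - margin] = "BACK"
    return out


def occupancy(
    series_list,
    angle_filter: tuple[float, float] | None = None,
    arena: tuple[float, float] = (30.0, 30.0),
    roi_margin: float = 5.0,
    cell_mm: float = 1.0,
    epochs: tuple[str, ...] | None = None,
) -> ArenaOccupancy:
    """Position histogram over all valid bins of one or more trials.

    ``angle_filter=(center, halfwidth)`` keeps only bins whose heading lies
    within ``center +/- halfwidth`` degrees (e.g. ``(0, 45)`` for the
    rheotaxis band); ``None`` keeps all angles.  An empty selection yields a
    flagged empty occupancy, not an exception.
    """
    if isinstance(series_list, KinematicSeries):
        series_list = [series_list]
    xs, ys = [], []
    for s in series_list:
        df = s.df
        # copy: to_numpy on a bool column may be a zero-copy view
        keep = df["valid"].to_numpy(dtype=bool).copy()
        if epochs is not None:
            keep &= df["epoch"].isin(epochs).to_numpy()
        if angle_filter is not None:
            c, hw = angle_filter
            dev = np.abs(wrap_degrees(df["heading"].to_numpy(dtype=float) - c))
            keep &= dev <= hw
        xs.append(df["x"].to_numpy(dtype=float)[keep])
        ys.append(df["y"].to_numpy(dtype=float)[keep])
    x = np.concatenate(xs) if xs else np.array([])
    y = np.concatenate(ys) if ys else np.array([])
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]

    w, h = arena
    if cell_mm <= 0 or roi_margin <= 0 or 2 * roi_margin > min(w, h):
        raise ParameterError("invalid cell size or ROI margin for this arena")
    x_edges = np.arange(0.0, w + cell_mm / 2, cell_mm)
    y_edges = np.arange(0.0, h + cell_mm / 2, cell_mm)
    grid, _, _ = np.histogram2d(x, y, bins=[x_edges, y_edges])
    n = int(x.size)
    if n == 0:
        return ArenaOccupancy(
            grid=grid,
            x_edges=x_edges,
            y_edges=y_edges,
            roi_fractions={k: 0.0 for k in ROI_NAMES},
            n=0,
            angle_filter=angle_filter,
            empty=True,
        )
    grid = grid / grid.sum()
    labels = classify_roi(x, y, arena=arena, margin=roi_margin)
    roi = {k: float(np.mean(labels == k)) for k in ROI_NAMES}
    return ArenaOccupancy(
        grid=grid,
        x_edges=x_edges,
        y_edges=y_edges,
        roi_fractions=roi,
        n=n,
        angle_filter=angle_filter,
    )
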