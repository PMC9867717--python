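"""Reading, calibrating, quality-controlling and time-binning pose tracks.

Accepted dialects
-----------------
* "wide": the three-level-header table exported by markerless trackers
  (scorer / bodyparts / coords rows, one column per keypoint coordinate),
  as CSV or HDF5.
* "long": a plain table with columns ``frame, bodypart, x, y[, likelihood]``.

Coordinates on disk are pixels; a ``px_per_mm`` calibration converts them to
mm on read.  Missing detections (empty cells, or likelihood below threshold)
become NaN and are never zero-filled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    KEYPOINTS,
    TREATMENTS,
    DataError,
    FormatError,
    InsufficientDataError,
    ParameterError,
    ScheduleError,
    StimulusSchedule,
)

#: fraction of missing samples above which the track is flagged, mirroring the
#: study's exclusion norm for missing data
MISSING_DATA_NORM = 0.04

DEFAULT_LIKELIHOOD_THRESHOLD = 0.6


@dataclass
class PoseTrack:
    """Calibrated per-frame keypoint coordinates for one trial.

    ``data`` is a frame-indexed DataFrame with MultiIndex columns
    ``(bodypart, coord)`` where coord is x / y (mm) and optionally
    likelihood.  NaN marks a missing detection.
    """

    trial_id: str
    treatment: str
    session: str
    fps: float
    px_per_mm: float
    data: pd.DataFrame
    arena: tuple[float, float] = (30.0, 30.0)

    def __post_init__(self) -> None:
        if self.px_per_mm <= 0:
            raise ParameterError("px_per_mm must be > 0")
        if self.fps <= 0:
            raise ParameterError("fps must be > 0")
        if self.treatment not in TREATMENTS:
            raise ParameterError(
                f"unknown treatment {self.treatment!r}; expected one of {TREATMENTS}"
            )
        parts = self.data.columns.get_level_values(0)
        missing = [k for k in KEYPOINTS if k not in set(parts)]
        if missing:
            raise FormatError(f"pose table lacks keypoint column(s): {missing}")

    @property
    def n_frames(self) -> int:
        return len(self.data)

    @property
    def times(self) -> np.ndarray:
        return np.asarray(self.data.index, dtype=float) / self.fps

    @property
    def duration(self) -> float:
        return self.n_frames / self.fps

    def xy(self, bodypart: str) -> np.ndarray:
        """(n_frames, 2) mm coordinates of one keypoint, NaN where missing."""
        return self.data[bodypart][["x", "y"]].to_numpy(dtype=float)

    def fraction_missing(self) -> float:
        """Fraction of (frame, keypoint) samples with no valid detection."""
        miss = 0
        for kp in KEYPOINTS:
            miss += int(np.isnan(self.xy(kp)).any(axis=1).sum())
        return miss / (self.n_frames * len(KEYPOINTS))


@dataclass
class QCReport:
    """Outcome of outlier correction on one track."""

    fraction_missing: float
    n_frames_flagged_outlier: int
    corrections_applied: list[tuple[int, str, str]] = field(default_factory=list)
    body_length_mm: float = float("nan")


@dataclass
class BinnedTrack:
    """Track resampled to fixed-width bins, labeled with stimulus epochs.

    Per-bin keypoint positions are means of valid frames.  The frame-level
    quantities the event classifier needs are pre-aggregated here:
    within-bin swim-bladder path length, net upstream displacement, and
    tail-tip amplitude about the body axis.
    """

    trial_id: str
    treatment: str
    session: str
    fps: float
    bin_s: float
    schedule: StimulusSchedule
    arena: tuple[float, float]
    bin_start: np.ndarray          # s, one per bin
    epoch: np.ndarray              # epoch name per bin
    pos: pd.DataFrame              # (bodypart, x/y) per-bin mean positions, mm
    n_valid: pd.DataFrame          # valid frame count per bin per bodypart
    path_mm: np.ndarray            # within-bin swim-bladder path length
    upstream_mm: np.ndarray        # within-bin net displacement toward upstream
    tail_amp_mm: np.ndarray        # within-bin peak-to-peak tail4 excursion

    @property
    def n_bins(self) -> int:
        return len(self.bin_start)

    def bin_xy(self, bodypart: str) -> np.ndarray:
        return self.pos[bodypart][["x", "y"]].to_numpy(dtype=float)

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format export: one row per bin x keypoint."""
        rows = []
        for kp in KEYPOINTS:
            xy = self.bin_xy(kp)
            rows.append(
                pd.DataFrame(
                    {
                        "trial_id": self.trial_id,
                        "bin_start_s": self.bin_start,
                        "epoch": self.epoch,
                        "keypoint": kp,
                        "x_mm": xy[:, 0],
                        "y_mm": xy[:, 1],
                        "n_valid_frames": self.n_valid[kp].to_numpy(),
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# reading / writing


def _read_wide(path: Path) -> pd.DataFrame:
    if path.suffix.lower() in {".h5", ".hdf5"}:
        df = pd.read_hdf(path)
        if not isinstance(df.columns, pd.MultiIndex):
            raise FormatError("HDF5 pose table must carry MultiIndex columns")
        # drop the scorer level if present
        if df.columns.nlevels == 3:
            df.columns = df.columns.droplevel(0)
        return df
    raw = pd.read_csv(path, header=[0, 1, 2], index_col=0)
    raw.columns = raw.columns.droplevel(0)
    return raw


def _read_long(path: Path) -> pd.DataFrame:
    raw = pd.read_csv(path)
    need = {"frame", "bodypart", "x", "y"}
    if not need.issubset(raw.columns):
        raise FormatError(f"long-format pose table needs columns {sorted(need)}")
    values = ["x", "y"] + (["likelihood"] if "likelihood" in raw.columns else [])
    wide = raw.pivot(index="frame", columns="bodypart", values=values)
    wide.columns = wide.columns.swaplevel(0, 1)
    return wide.sort_index(axis=1)


def _sniff_dialect(path: Path) -> str:
    if path.suffix.lower() in {".h5", ".hdf5"}:
        return "wide"
    with open(path) as fh:
        first = fh.readline()
    cols = [c.strip() for c in first.split(",")]
    return "long" if "bodypart" in cols else "wide"


def read_pose_table(
    path,
    *,
    trial_id: str,
    treatment: str,
    session: str = "",
    fps: float,
    px_per_mm: float,
    arena: tuple[float, float] = (30.0, 30.0),
    likelihood_threshold: float = DEFAULT_LIKELIHOOD_THRESHOLD,
) -> PoseTrack:
    """Read a pose table and return a calibrated :class:`PoseTrack` in mm.

    ``fps`` comes from trial metadata (never inferred from the file).
    Samples with likelihood below ``likelihood_threshold`` are treated as
    missing.  Raises :class:`FormatError` for a missing keypoint column,
    :class:`DataError` for a non-monotone frame index, and
    :class:`ParameterError` for a non-positive calibration.
    """
    path = Path(path)
    if px_per_mm <= 0:
        raise ParameterError("px_per_mm must be > 0")
    raw = _read_long(path) if _sniff_dialect(path) == "long" else _read_wide(path)

    parts = set(raw.columns.get_level_values(0))
    missing = [k for k in KEYPOINTS if k not in parts]
    if missing:
        raise FormatError(f"pose table lacks keypoint column(s): {missing}")

    idx = np.asarray(raw.index, dtype=float)
    if len(idx) > 1 and np.any(np.diff(idx) <= 0):
        raise DataError("frame index must be strictly increasing")

    cols = {}
    for kp in KEYPOINTS:
        x = pd.to_numeric(raw[kp]["x"], errors="coerce").to_numpy(dtype=float)
        y = pd.to_numeric(raw[kp]["y"], errors="coerce").to_numpy(dtype=float)
        if "likelihood" in raw[kp].columns:
            lik = pd.to_numeric(raw[kp]["likelihood"], errors="coerce").to_numpy(
                dtype=float
            )
            bad = ~(lik >= likelihood_threshold)  # NaN likelihood -> missing
            x = np.where(bad, np.nan, x)
            y = np.where(bad, np.nan, y)
            cols[(kp, "likelihood")] = lik
        cols[(kp, "x")] = x / px_per_mm
        cols[(kp, "y")] = y / px_per_mm
    data = pd.DataFrame(cols, index=pd.RangeIndex(len(raw), name="frame"))
    data.columns = pd.MultiIndex.from_tuples(data.columns, names=["bodypart", "coord"])
    data = data.sort_index(axis=1)
    return PoseTrack(
        trial_id=trial_id,
        treatment=treatment,
        session=session,
        fps=fps,
        px_per_mm=px_per_mm,
        data=data,
        arena=arena,
    )


def write_pose_table(track: PoseTrack, path, dialect: str = "wide") -> Path:
    """Write a track back to pixels in one of the accepted dialects.

    Full float precision is kept so a write-then-read round trip reproduces
    the coordinates to well below 1e-9 mm.
    """
    path = Path(path)
    k = track.px_per_mm
    if dialect == "wide":
        cols = {}
        for kp in KEYPOINTS:
            xy = track.xy(kp)
            cols[("rheokit", kp, "x")] = xy[:, 0] * k
            cols[("rheokit", kp, "y")] = xy[:, 1] * k
            if (kp, "likelihood") in track.data.columns:
                cols[("rheokit", kp, "likelihood")] = track.data[(kp, "likelihood")]
            else:
                cols[("rheokit", kp, "likelihood")] = np.where(
                    np.isnan(xy).any(axis=1), 0.0, 1.0
                )
        out = pd.DataFrame(cols, index=track.data.index)
        out.columns.names = ["scorer", "bodyparts", "coords"]
        out.to_csv(path)
    elif dialect == "long":
        rows = []
        for kp in KEYPOINTS:
            xy = track.xy(kp)
            rows.append(
                pd.DataFrame(
                    {
                        "frame": np.asarray(track.data.index),
                        "bodypart": kp,
                        "x": xy[:, 0] * k,
                        "y": xy[:, 1] * k,
                        "likelihood": np.where(np.isnan(xy).any(axis=1), 0.0, 1.0),
                    }
                )
            )
        pd.concat(rows, ignore_index=True).to_csv(path, index=False)
    else:
        raise ParameterError(f"unknown dialect {dialect!r}")
    return path


# ---------------------------------------------------------------------------
# quality control


def _eye_mid(track: PoseTrack) -> np.ndarray:
    le, re = track.xy("left_eye"), track.xy("right_eye")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        return np.nanmean(np.stack([le, re]), axis=0)


def estimate_body_length(track: PoseTrack) -> float:
    """Median eye-midpoint -> tail4 distance over frames with both valid."""
    mid = _eye_mid(track)
    tail = track.xy("tail4")
    d = np.hypot(*(mid - tail).T)
    d = d[np.isfinite(d)]
    if d.size == 0:
        raise InsufficientDataError("no frame with both eye and tail4 valid")
    return float(np.median(d))


def qc_track(
    track: PoseTrack,
    movement_criterion: float = 0.7,
    location_criterion: float = 1.5,
) -> tuple[PoseTrack, QCReport]:
    """Flag and hold-last-correct outlier keypoint samples.

    A sample is an outlier when its displacement from the keypoint's last
    accepted value exceeds ``movement_criterion`` body lengths, or its
    distance from the frame's body centroid exceeds ``location_criterion``
    body lengths.  Flagged samples are replaced by the keypoint's last
    accepted value.  ``fraction_missing`` is computed before corrections and
    a warning is issued when it exceeds the 4% missing-data norm.
    """
    if movement_criterion <= 0 or location_criterion <= 0:
        raise ParameterError("QC criteria must be > 0")
    n_valid_frames = (~np.isnan(track.xy("swim_bladder")).any(axis=1)).sum()
    if track.n_frames < 2 or n_valid_frames < 2:
        raise InsufficientDataError("QC needs at least 2 valid frames")

    frac_missing = track.fraction_missing()
    if frac_missing > MISSING_DATA_NORM:
        warnings.warn(
            f"track {track.trial_id}: {frac_missing:.1%} of samples missing "
            f"exceeds the {MISSING_DATA_NORM:.0%} missing-data norm",
            stacklevel=2,
        )

    bl = estimate_body_length(track)
    move_thr = movement_criterion * bl
    loc_thr = location_criterion * bl

    arrs = {kp: track.xy(kp).copy() for kp in KEYPOINTS}
    n = track.n_frames
    corrections: list[tuple[int, str, str]] = []
    flagged_frames: set[int] = set()
    last_good = {kp: None for kp in KEYPOINTS}

    for i in range(n):
        frame_vals = np.array(
            [arrs[kp][i] for kp in KEYPOINTS], dtype=float
        )  # raw values this frame
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            # median centroid: robust to a single teleported keypoint
            centroid = np.nanmedian(frame_vals, axis=0)
        for kp in KEYPOINTS:
            v = arrs[kp][i]
            if np.isnan(v).any():
                continue
            rule = None
            lg = last_good[kp]
            if lg is not None and np.hypot(*(v - lg)) > move_thr:
                rule = "movement"
            elif np.isfinite(centroid).all() and np.hypot(*(v - centroid)) > loc_thr:
                rule = "location"
            if rule is not None:
                if lg is not None:
                    arrs[kp][i] = lg
                corrections.append((i, kp, rule))
                flagged_frames.add(i)
            else:
                last_good[kp] = v.copy()

    data = track.data.copy()
    for kp in KEYPOINTS:
        data[(kp, "x")] = arrs[kp][:, 0]
        data[(kp, "y")] = arrs[kp][:, 1]
    corrected = replace(track, data=data)
    report = QCReport(
        fraction_missing=frac_missing,
        n_frames_flagged_outlier=len(flagged_frames),
        corrections_applied=corrections,
        body_length_mm=bl,
    )
    return corrected, report


# ---------------------------------------------------------------------------
# binning


def bin_track(
    track: PoseTrack,
    schedule: StimulusSchedule | None = None,
    bin_ms: float = 100.0,
) -> BinnedTrack:
    """Quantize a track into fixed-width bins labeled with stimulus epochs.

    ``bin_ms`` must be an integer multiple of the frame period (20 frames
    per 100-ms bin at 200 fps, 6 at 60 fps).  Per-bin keypoint positions
    are means over valid frames; a bin with zero valid frames is missing
    (NaN).  Bins never straddle epoch boundaries, which requires the
    schedule's epoch edges to lie on the bin grid.
    """
    schedule = schedule or StimulusSchedule()
    frames_per_bin = bin_ms * track.fps / 1000.0
    if not np.isclose(frames_per_bin, round(frames_per_bin)):
        raise ParameterError(
            f"bin_ms={bin_ms} is not an integer multiple of the frame period "
            f"at {track.fps} fps"
        )
    fpb = int(round(frames_per_bin))
    bin_s = bin_ms / 1000.0
    if track.duration > schedule.duration + 1e-9:
        raise ScheduleError("schedule does not cover the track duration")
    for ep in schedule.epochs:
        for edge in (ep.start, ep.end):
            if not np.isclose(np.round(edge / bin_s), edge / bin_s):
                raise ScheduleError("epoch boundaries must lie on the bin grid")

    n_bins = int(np.ceil(track.n_frames / fpb))
    bin_idx = np.arange(track.n_frames) // fpb
    bin_start = schedule.start + np.arange(n_bins) * bin_s
    epoch = schedule.epoch_of(bin_start + bin_s / 2.0)

    pos_cols, nval_cols = {}, {}
    for kp in KEYPOINTS:
        xy = track.xy(kp)
        valid = ~np.isnan(xy).any(axis=1)
        cnt = np.bincount(bin_idx, weights=valid, minlength=n_bins)
        sx = np.bincount(bin_idx, weights=np.where(valid, xy[:, 0], 0.0), minlength=n_bins)
        sy = np.bincount(bin_idx, weights=np.where(valid, xy[:, 1], 0.0), minlength=n_bins)
        with np.errstate(invalid="ignore", divide="ignore"):
            mx = np.where(cnt > 0, sx / cnt, np.nan)
            my = np.where(cnt > 0, sy / cnt, np.nan)
        pos_cols[(kp, "x")] = mx
        pos_cols[(kp, "y")] = my
        nval_cols[kp] = cnt.astype(int)
    pos = pd.DataFrame(pos_cols)
    pos.columns = pd.MultiIndex.from_tuples(pos.columns, names=["bodypart", "coord"])
    n_valid = pd.DataFrame(nval_cols)

    path_mm, upstream_mm, tail_amp_mm = _within_bin_features(
        track, schedule, bin_idx, n_bins
    )

    return BinnedTrack(
        trial_id=track.trial_id,
        treatment=track.treatment,
        session=track.session,
        fps=track.fps,
        bin_s=bin_s,
        schedule=schedule,
        arena=track.arena,
        bin_start=bin_start,
        epoch=epoch,
        pos=pos,
        n_valid=n_valid,
        path_mm=path_mm,
        upstream_mm=upstream_mm,
        tail_amp_mm=tail_amp_mm,
    )


def _within_bin_features(track, schedule, bin_idx, n_bins):
    """Swim-bladder path length, upstream net displacement, tail amplitude."""
    sb = track.xy("swim_bladder")
    valid = ~np.isnan(sb).any(axis=1)
    up = schedule.upstream

    # path length over consecutive valid frame pairs; each step is assigned
    # to the bin of its first frame, so per-bin distances sum to the total
    # path length (uniform motion of 1 mm per bin reads exactly 1 mm)
    step = np.hypot(*np.diff(sb, axis=0).T)
    pair_ok = valid[:-1] & valid[1:]
    path_mm = np.bincount(
        bin_idx[:-1], weights=np.where(pair_ok, step, 0.0), minlength=n_bins
    )

    # net displacement first->last valid frame in the bin, projected upstream
    upstream_mm = np.zeros(n_bins)
    idx_valid = np.flatnonzero(valid)
    if idx_valid.size:
        first = np.full(n_bins, -1, dtype=int)
        last = np.full(n_bins, -1, dtype=int)
        for i in idx_valid:  # bins are short; simple scan
            b = bin_idx[i]
            if first[b] < 0:
                first[b] = i
            last[b] = i
        ok = first >= 0
        disp = np.zeros((n_bins, 2))
        disp[ok] = sb[last[ok]] - sb[first[ok]]
        upstream_mm = disp @ up
    path_mm = np.where(np.bincount(bin_idx, weights=valid, minlength=n_bins) > 0,
                       path_mm, np.nan)
    upstream_mm = np.where(np.isnan(path_mm), np.nan, upstream_mm)

    # tail-tip lateral excursion about the bin-mean body axis; a per-frame
    # axis would leak eye/bladder jitter into the tail amplitude through
    # the tail's long lever arm
    mid = _eye_mid(track)
    rel = track.xy("tail4") - sb
    tail_amp_mm = np.full(n_bins, np.nan)
    axis_ok = np.isfinite(mid).all(axis=1) & valid
    rel_ok = np.isfinite(rel).all(axis=1)
    for b in range(n_bins):
        sel = bin_idx == b
        a_sel = sel & axis_ok
        if a_sel.sum() == 0:
            continue
        axis = (mid[a_sel] - sb[a_sel]).mean(axis=0)
        norm = np.hypot(*axis)
        if norm == 0:
            continue
        axis = axis / norm
        r_sel = sel & rel_ok
        if r_sel.sum() >= 2:
            lateral = rel[r_sel, 0] * axis[1] - rel[r_sel, 1] * axis[0]
            tail_amp_mm[b] = lateral.max() - lateral.min()
        elif r_sel.sum() == 1:
            tail_amp_mm[b] = 0.0
    return np.asarray(path_mm, float), np.asarray(upstream_mm, float), tail_amp_mm
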