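"""Shared fixtures: schedule, scripted-track builders, tiny pose tables."""

import numpy as np
import pandas as pd
import pytest

from rheokit.core import KEYPOINTS, StimulusSchedule
from rheokit.simulate import scripted_track


@pytest.fixture
def schedule():
    return StimulusSchedule()


def drift_track(fps=60.0, flow_speed=9.74, duration=30.0, heading=0.0):
    """Fish facing a fixed heading, passively drifting downstream during
    flow (tail rigid): must never classify as rheotaxis."""
    n = int(duration * fps)
    t = np.arange(n) / fps
    vy = np.where((t >= 10.0) & (t < 30.0), flow_speed, 0.0)
    y = 5.0 + np.cumsum(vy) / fps
    y = np.minimum(y, 29.0)  # park at the rear instead of leaving the arena
    sb = np.stack([np.full(n, 15.0), y], axis=1)
    return scripted_track(sb, np.full(n, heading), fps=fps)


def swimming_track(
    compliant,
    fps=60.0,
    heading_in=10.0,
    heading_out=120.0,
    upstream_speed=5.0,
):
    """Fish swimming upstream with an oscillating tail exactly where
    ``compliant`` (per-frame bool) is True, badly oriented and stationary
    elsewhere."""
    compliant = np.asarray(compliant, dtype=bool)
    n = compliant.size
    heading = np.where(compliant, heading_in, heading_out)
    vy = np.where(compliant, -upstream_speed, 0.0)
    y = 27.0 + np.cumsum(vy) / fps
    sb = np.stack([np.full(n, 15.0), y], axis=1)
    return scripted_track(sb, heading, fps=fps, tail_wiggle=compliant)


def wide_pose_csv(path, frames, px=100.0, missing=()):
    """Write a minimal three-level-header pose table; ``missing`` is a set
    of (frame, keypoint) cells left empty."""
    cols = pd.MultiIndex.from_tuples(
        [("scorer", kp, c) for kp in KEYPOINTS for c in ("x", "y", "likelihood")],
        names=["scorer", "bodyparts", "coords"],
    )
    data = []
    for f in range(frames):
        row = []
        for kp in KEYPOINTS:
            if (f, kp) in missing:
                row += [np.nan, np.nan, 0.0]
            else:
                row += [px, px, 0.99]
        data.append(row)
    pd.DataFrame(data, columns=cols).to_csv(path)
    return path
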