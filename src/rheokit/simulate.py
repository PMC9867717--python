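"""Synthetic burst-and-glide swimmer with known ground truth.

The generator emulates a single larval zebrafish in a 30 x 30 mm arena:
spontaneous burst-and-glide locomotion (Poisson bursts with exponentially
decaying glide speed), a freeze-then-respond reaction to flow onset with a
stochastic latency, von Mises heading control toward upstream while
responsive, random-walk heading otherwise, passive downstream advection at
the flow speed whenever the fish is not actively swimming, an optional
deterministic periodic modulation of burst vigor, and a planted lead/lag
(in 100-ms bins) between heading changes and the bursts they accompany.

Heading re-draws are quantized to the 100-ms analysis grid so the planted
lag is expressed exactly in bins.  Hitting a wall triggers a heading
re-draw in the fish's current behavioral state; motion that keeps pushing
into a wall slides along it.  A sticky rear wall that pins drifting fish
against the downstream mesh is available as an option.

Every trial is a pure function of its seed: identical seeds give
bit-identical tracks.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .core import KEYPOINTS, ParameterError, StimulusSchedule, wrap_degrees
from .track_io import PoseTrack, write_pose_table

#: geometry of the model larva, mm
BODY_AXIS_MM = 0.8          # swim bladder -> eye midpoint
EYE_OFFSET_MM = 0.25        # half inter-eye distance
TAIL_SPACING_MM = 0.7       # spacing of tail1..tail4 behind the bladder
ACTIVE_CUTOFF_FRACTION = 0.02  # of burst_speed: below this the fish glides


@dataclass(frozen=True)
class SwimmerProfile:
    """Generative parameters of one synthetic swimmer."""

    burst_rate: float = 1.0        # bursts / s
    burst_speed: float = 25.0      # mm / s peak active speed
    glide_decay: float = 5.0       # 1 / s exponential speed decay
    heading_kappa: float = 8.0     # von Mises concentration toward upstream
    heading_sd_noflow: float = 40.0  # deg random-walk step off stimulus
    latency_mean: float = 0.5      # s from flow onset to response
    latency_sd: float = 0.2        # s
    periodic_freq: float = 0.0     # Hz modulation of burst vigor (0 = none)
    periodic_amp: float = 0.0      # relative modulation amplitude
    angular_lag: int = 0           # bins: heading change after (+) / before (-)
                                   # the accompanying burst
    tail_beat_freq: float = 20.0   # Hz, during bursts only
    tail_beat_amp: float = 0.8     # mm lateral tail-tip amplitude
    drift: bool = True             # advect downstream at flow speed when gliding
    keypoint_noise_mm: float = 0.0
    missing_rate: float = 0.0      # per-frame chance one keypoint drops out
    wall_mode: str = "reflect"     # "reflect" | "sticky_rear"
    bin_s: float = 0.1             # grid on which heading changes are applied

    def __post_init__(self) -> None:
        for name in ("burst_rate", "burst_speed", "glide_decay",
                     "heading_kappa", "heading_sd_noflow", "latency_mean",
                     "latency_sd", "periodic_freq", "periodic_amp",
                     "tail_beat_freq", "tail_beat_amp",
                     "keypoint_noise_mm", "missing_rate"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if self.wall_mode not in ("reflect", "sticky_rear"):
            raise ParameterError("wall_mode must be 'reflect' or 'sticky_rear'")


@dataclass
class SimulatedTrial:
    track: PoseTrack
    profile: SwimmerProfile
    schedule: StimulusSchedule
    seed: int
    truth: dict  # latency_s, response_time_s, burst_times_s, events, ...


def preset_profiles() -> dict[str, SwimmerProfile]:
    """Named profiles whose cohorts reproduce the qualitative group
    signatures: controls hold station with tight upstream heading and long
    events; copper-like fish respond late with a large slow modulation of
    movement; neomycin-like fish fragment into many short events with
    erratic headings and a single planted 0.21-Hz movement modulation.

    These numbers are declared fixtures for testing the pipeline, not
    estimates of real fish.
    """
    return {
        "control_like": SwimmerProfile(
            burst_rate=1.0, burst_speed=25.0, glide_decay=5.0,
            heading_kappa=10.0, heading_sd_noflow=40.0,
            latency_mean=0.3, latency_sd=0.15,
            periodic_freq=0.9, periodic_amp=0.10, angular_lag=-1,
            keypoint_noise_mm=0.02, missing_rate=0.005,
        ),
        "cuso4_like": SwimmerProfile(
            burst_rate=0.8, burst_speed=28.0, glide_decay=5.0,
            heading_kappa=4.5, heading_sd_noflow=40.0,
            latency_mean=2.0, latency_sd=0.5,
            periodic_freq=0.15, periodic_amp=0.50, angular_lag=2,
            keypoint_noise_mm=0.02, missing_rate=0.005,
        ),
        "neomycin_like": SwimmerProfile(
            burst_rate=2.6, burst_speed=25.0, glide_decay=5.0,
            heading_kappa=3.5, heading_sd_noflow=40.0,
            latency_mean=0.5, latency_sd=0.2,
            periodic_freq=0.21, periodic_amp=0.45, angular_lag=1,
            keypoint_noise_mm=0.02, missing_rate=0.005,
        ),
    }


def simulate_trial(
    profile: SwimmerProfile,
    schedule: StimulusSchedule | None = None,
    fps: float = 60.0,
    seed: int = 0,
    arena: tuple[float, float] = (30.0, 30.0),
    px_per_mm: float = 10.0,
    trial_id: str = "sim",
    treatment: str = "custom",
    session: str = "sim",
    require_response: bool = False,
) -> SimulatedTrial:
    """Simulate one trial and return the pose track plus ground truth."""
    schedule = schedule or StimulusSchedule()
    if seed is None:
        raise ParameterError("seed is mandatory")
    rng = np.random.default_rng(seed)
    T = schedule.duration
    dt = 1.0 / fps
    n = int(round(T * fps))
    t = schedule.start + np.arange(n) * dt
    flow_on = schedule.flow_on(t)
    has_flow = len(schedule.flow_epochs()) > 0

    # --- latency / response time -----------------------------------------
    latency = max(0.0, rng.normal(profile.latency_mean, profile.latency_sd))
    if has_flow:
        onset = schedule.flow_onset
        response_time = onset + latency
        if require_response and response_time >= schedule.flow_epochs()[-1].end:
            raise ParameterError("latency exceeds the flow presentation")
    else:
        response_time = np.inf

    # --- burst times -------------------------------------------------------
    # burst onsets are quantized to the analysis grid (like heading changes)
    # so planted lags and latencies are expressed exactly in bins
    bin_s = profile.bin_s
    n_bursts = rng.poisson(profile.burst_rate * T)
    bursts = np.sort(rng.uniform(schedule.start, schedule.end, size=n_bursts))
    if has_flow:
        # freeze between flow onset and the response: no new bursts
        keep = (bursts < onset) | (bursts >= response_time)
        bursts = bursts[keep]
    bursts = np.floor(bursts / bin_s + 1e-9) * bin_s
    if has_flow:
        response_time = max(onset, np.floor(response_time / bin_s) * bin_s)
        if response_time < schedule.end and profile.burst_rate > 0:
            bursts = np.sort(np.append(bursts, response_time))
    responsive_burst = flow_mask_of(bursts, schedule) & (bursts >= response_time - 1e-9)

    # --- heading-change sequence ------------------------------------------
    # each burst carries a heading change placed angular_lag bins after the
    # burst's bin; the response burst turns immediately
    change_bin = np.round(bursts / bin_s).astype(np.int64) + profile.angular_lag
    if has_flow and profile.burst_rate > 0 and response_time < schedule.end:
        i_resp = int(np.searchsorted(bursts, response_time - 1e-9))
        if i_resp < bursts.size and np.isclose(bursts[i_resp], response_time):
            change_bin[i_resp] = int(np.round(response_time / bin_s))
    change_time = change_bin * bin_s
    order = np.argsort(change_time, kind="stable")
    change_time = change_time[order]
    change_resp = responsive_burst[order]

    # --- active speed ------------------------------------------------------
    j = np.searchsorted(bursts, t, side="right") - 1
    speed = np.zeros(n)
    okb = j >= 0
    speed[okb] = profile.burst_speed * np.exp(
        -profile.glide_decay * (t[okb] - bursts[j[okb]])
    )
    if has_flow:
        speed[flow_on & (t < response_time)] = 0.0  # freeze after flow onset
    if profile.periodic_freq > 0 and profile.periodic_amp > 0:
        speed = speed * np.clip(
            1.0 + profile.periodic_amp * np.sin(2 * np.pi * profile.periodic_freq * t),
            0.0,
            None,
        )
    active = speed > ACTIVE_CUTOFF_FRACTION * max(profile.burst_speed, 1e-9)

    # --- trajectory with wall interaction ----------------------------------
    # Event-driven integration: the path is integrated vectorized between
    # heading changes; hitting a wall triggers a heading re-draw (von Mises
    # while responsive, random-walk step otherwise).  A fish whose heading
    # or drift keeps pushing into a wall slides along it (the rear-mesh
    # pinning phenomenology) instead of re-colliding every frame.
    gliding = (flow_on & ~active) if profile.drift else np.zeros(n, dtype=bool)
    drift_v = np.where(gliding, schedule.flow_speed, 0.0)
    w, hgt = arena
    sticky = profile.wall_mode == "sticky_rear"
    resp_frame = flow_on & (t >= response_time)

    def draw_heading(prev: float, responsive: bool) -> float:
        if responsive:
            return float(
                np.degrees(rng.vonmises(0.0, max(profile.heading_kappa, 1e-9)))
            )
        return float(wrap_degrees(prev + rng.normal(0.0, profile.heading_sd_noflow)))

    seg_edges = np.unique(np.concatenate(
        [[0], np.clip(np.searchsorted(t, change_time, side="left"), 0, n), [n]]
    ))
    seg_resp = {}
    for ct, cr in zip(change_time, change_resp):
        seg_resp[int(np.clip(np.searchsorted(t, ct, side="left"), 0, n))] = bool(cr)

    h = rng.uniform(-180.0, 180.0)
    h_arr = np.empty(n)
    sb = np.empty((n, 2))
    pos = np.array([w / 2.0, hgt / 2.0])
    eps = 1e-9
    for a, b in zip(seg_edges[:-1], seg_edges[1:]):
        if a == b:
            continue
        if a in seg_resp:
            h = draw_heading(h, seg_resp[a])
        i = a
        while i < b:
            hr = np.radians(h)
            dx, dy = np.sin(hr), -np.cos(hr)
            vx = speed[i:b] * dx
            vy = speed[i:b] * dy + drift_v[i:b]
            # slide along a wall the motion keeps pushing into
            if (pos[0] <= eps and vx[0] < 0) or (pos[0] >= w - eps and vx[0] > 0):
                vx = np.zeros_like(vx)
            if (pos[1] <= eps and vy[0] < 0) or (pos[1] >= hgt - eps and vy[0] > 0):
                vy = np.zeros_like(vy)
            steps = np.cumsum(np.stack([vx, vy], axis=1) * dt, axis=0)
            p = pos + np.vstack([[0.0, 0.0], steps[:-1]])
            out = (p[:, 0] < 0) | (p[:, 0] > w) | (p[:, 1] < 0) | (p[:, 1] > hgt)
            hit = np.flatnonzero(out)
            if hit.size == 0:
                sb[i:b] = p
                h_arr[i:b] = h
                pos = np.clip(pos + steps[-1], [0.0, 0.0], [w, hgt])
                i = b
                continue
            k = i + int(hit[0])
            sb[i:k] = p[: k - i]
            h_arr[i:k] = h
            pos = np.clip(p[k - i], [0.0, 0.0], [w, hgt])
            rear_pin = sticky and pos[1] >= hgt - eps
            if not rear_pin:
                h = draw_heading(h, bool(resp_frame[k]))
            sb[k] = pos
            h_arr[k] = h
            hr = np.radians(h)
            v_k = np.array([
                speed[k] * np.sin(hr),
                -speed[k] * np.cos(hr) + drift_v[k],
            ])
            pos = np.clip(pos + v_k * dt, [0.0, 0.0], [w, hgt])
            i = k + 1
    eff_dir = np.stack(
        [np.sin(np.radians(h_arr)), -np.cos(np.radians(h_arr))], axis=1
    )
    eff_heading = h_arr.copy()

    # --- keypoints ----------------------------------------------------------
    perp = np.stack([-eff_dir[:, 1], eff_dir[:, 0]], axis=1)
    phase = rng.uniform(0, 2 * np.pi)
    beat = np.where(
        active, np.sin(2 * np.pi * profile.tail_beat_freq * t + phase), 0.0
    )
    kps = {
        "swim_bladder": sb,
        "left_eye": sb + BODY_AXIS_MM * eff_dir + EYE_OFFSET_MM * perp,
        "right_eye": sb + BODY_AXIS_MM * eff_dir - EYE_OFFSET_MM * perp,
    }
    tail_lateral = None
    for i in range(1, 5):
        amp = profile.tail_beat_amp * i / 4.0
        lateral = amp * beat
        kps[f"tail{i}"] = sb - TAIL_SPACING_MM * i * eff_dir + lateral[:, None] * perp
        if i == 4:
            tail_lateral = lateral

    noise = profile.keypoint_noise_mm
    lik = {kp: np.full(n, 0.99) for kp in KEYPOINTS}
    if noise > 0:
        for kp in KEYPOINTS:
            kps[kp] = kps[kp] + rng.normal(0.0, noise, size=(n, 2))
    if profile.missing_rate > 0:
        drop = rng.random(n) < profile.missing_rate
        which = rng.integers(0, len(KEYPOINTS), size=n)
        for ki, kp in enumerate(KEYPOINTS):
            lik[kp][drop & (which == ki)] = 0.1

    cols = {}
    for kp in KEYPOINTS:
        cols[(kp, "x")] = kps[kp][:, 0]
        cols[(kp, "y")] = kps[kp][:, 1]
        cols[(kp, "likelihood")] = lik[kp]
    data = pd.DataFrame(cols, index=pd.RangeIndex(n, name="frame"))
    data.columns = pd.MultiIndex.from_tuples(data.columns,
                                             names=["bodypart", "coord"])
    data = data.sort_index(axis=1)
    for kp in KEYPOINTS:  # apply dropouts as missing coordinates
        bad = lik[kp] < 0.6
        data.loc[bad, (kp, "x")] = np.nan
        data.loc[bad, (kp, "y")] = np.nan

    track = PoseTrack(
        trial_id=trial_id,
        treatment=treatment,
        session=session,
        fps=fps,
        px_per_mm=px_per_mm,
        data=data.sort_index(axis=1),
        arena=arena,
    )

    truth = _ground_truth(
        t, sb, eff_heading, tail_lateral, active, flow_on, schedule,
        bin_s, latency if has_flow else np.nan,
        response_time, bursts, profile,
    )
    return SimulatedTrial(track=track, profile=profile, schedule=schedule,
                          seed=int(seed), truth=truth)


def flow_mask_of(times: np.ndarray, schedule: StimulusSchedule) -> np.ndarray:
    return schedule.flow_on(times)


def _ground_truth(t, sb, eff_heading, tail_lateral, active, flow_on,
                  schedule, bin_s, latency, response_time, bursts, profile):
    """Apply the event rule to the noiseless internal state, per 100-ms bin."""
    n_bins = int(round((t[-1] + (t[1] - t[0]) - schedule.start) / bin_s))
    bin_idx = np.minimum(((t - schedule.start) / bin_s).astype(np.int64),
                         n_bins - 1)
    hr = np.radians(eff_heading)
    cs = np.bincount(bin_idx, weights=np.cos(hr), minlength=n_bins)
    sn = np.bincount(bin_idx, weights=np.sin(hr), minlength=n_bins)
    bin_heading = wrap_degrees(np.degrees(np.arctan2(sn, cs)))
    in_band = np.abs(bin_heading) <= 45.0

    p2p = np.zeros(n_bins)
    upstream = np.zeros(n_bins)
    up = schedule.upstream
    for b in range(n_bins):
        sel = bin_idx == b
        lat = tail_lateral[sel]
        if lat.size >= 2:
            p2p[b] = lat.max() - lat.min()
        i0, i1 = np.flatnonzero(sel)[[0, -1]]
        upstream[b] = (sb[i1] - sb[i0]) @ up
    t_mid = schedule.start + (np.arange(n_bins) + 0.5) * bin_s
    bin_flow = schedule.flow_on(t_mid)
    crit = in_band & np.where(bin_flow, (p2p >= 0.3) & (upstream > 0), True)

    events = []
    i = 0
    while i < n_bins:
        if not crit[i]:
            i += 1
            continue
        j = i
        while j + 1 < n_bins and crit[j + 1]:
            j += 1
        events.append((schedule.start + i * bin_s,
                       schedule.start + (j + 1) * bin_s))
        i = j + 1
    flow_events = [e for e in events if e[1] > schedule.flow_onset] \
        if schedule.flow_epochs() else []
    first = min((max(e[0], schedule.flow_onset) for e in flow_events),
                default=np.nan)
    return {
        "latency_s": float(latency),
        "response_time_s": float(response_time),
        "first_event_time_s": float(first),
        "burst_times_s": [float(b) for b in bursts],
        "events": [(float(a), float(b)) for a, b in events],
        "planted_periodic_freq_hz": profile.periodic_freq,
        "planted_angular_lag_bins": profile.angular_lag,
        "planted_heading_kappa": profile.heading_kappa,
    }


def scripted_track(
    sb_xy: np.ndarray,
    heading_deg: np.ndarray,
    fps: float = 60.0,
    tail_wiggle: np.ndarray | None = None,
    tail_beat_freq: float = 20.0,
    tail_beat_amp: float = 0.8,
    trial_id: str = "scripted",
    treatment: str = "custom",
    session: str = "scripted",
    px_per_mm: float = 10.0,
    arena: tuple[float, float] = (30.0, 30.0),
) -> PoseTrack:
    """Build a fully deterministic track from prescribed per-frame
    swim-bladder positions and headings (for constructing edge cases:
    passive drift, sub-bout compliance, rigid-tail swimming, ...).

    ``tail_wiggle`` is a per-frame boolean mask: where True the tail
    oscillates at ``tail_beat_freq``; elsewhere it is rigid.
    """
    sb = np.asarray(sb_xy, dtype=float)
    heading = np.asarray(heading_deg, dtype=float)
    n = len(sb)
    if heading.shape != (n,):
        raise ParameterError("heading_deg must match sb_xy length")
    t = np.arange(n) / fps
    if tail_wiggle is None:
        tail_wiggle = np.zeros(n, dtype=bool)
    hr = np.radians(heading)
    d = np.stack([np.sin(hr), -np.cos(hr)], axis=1)
    perp = np.stack([-d[:, 1], d[:, 0]], axis=1)
    beat = np.where(tail_wiggle, np.sin(2 * np.pi * tail_beat_freq * t), 0.0)
    cols = {}
    kp_pos = {
        "swim_bladder": sb,
        "left_eye": sb + BODY_AXIS_MM * d + EYE_OFFSET_MM * perp,
        "right_eye": sb + BODY_AXIS_MM * d - EYE_OFFSET_MM * perp,
    }
    for i in range(1, 5):
        lateral = tail_beat_amp * i / 4.0 * beat
        kp_pos[f"tail{i}"] = sb - TAIL_SPACING_MM * i * d + lateral[:, None] * perp
    for kp in KEYPOINTS:
        cols[(kp, "x")] = kp_pos[kp][:, 0]
        cols[(kp, "y")] = kp_pos[kp][:, 1]
        cols[(kp, "likelihood")] = np.full(n, 0.99)
    data = pd.DataFrame(cols, index=pd.RangeIndex(n, name="frame"))
    data.columns = pd.MultiIndex.from_tuples(data.columns,
                                             names=["bodypart", "coord"])
    return PoseTrack(
        trial_id=trial_id, treatment=treatment, session=session, fps=fps,
        px_per_mm=px_per_mm, data=data.sort_index(axis=1), arena=arena,
    )


def write_trial(trial: SimulatedTrial, out_dir, dialect: str = "wide") -> dict:
    """Write the pose table plus a ground-truth JSON sidecar; return the
    manifest row describing the files."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    track_path = out_dir / f"{trial.track.trial_id}.csv"
    write_pose_table(trial.track, track_path, dialect=dialect)
    sidecar = out_dir / f"{trial.track.trial_id}.truth.json"
    payload = dict(trial.truth)
    payload["seed"] = trial.seed
    payload["profile"] = asdict(trial.profile)
    with open(sidecar, "w") as fh:
        json.dump(payload, fh, indent=1)
    return {
        "trial_id": trial.track.trial_id,
        "path": track_path.name,
        "truth_path": sidecar.name,
        "treatment": trial.track.treatment,
        "session": trial.track.session,
        "fps": trial.track.fps,
        "px_per_mm": trial.track.px_per_mm,
    }
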