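"""End-to-end orchestration: cohort simulation, per-trial processing, and
the per-group report tables (orientation, events, spatial use, responder
curves, decompositions, spectra, net shifts, cross-correlograms).

A run is a pure function of (inputs, config, seed); the config hash is
stamped into every output table so outputs are traceable to the exact
configuration that produced them.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .circstats import mean_resultant, per_fish_means, v_test, watson_wheeler
from .core import ConfigError, DataError, StimulusSchedule
from .events import classify_events, responder_curve, summarize_events
from .kinematics import KinematicSeries, linear_series, occupancy
from .simulate import SwimmerProfile, preset_profiles, simulate_trial, write_trial
from .spectral import cross_correlate, decompose, dominant_peaks, net_shift, periodogram
from .track_io import bin_track, qc_track, read_pose_table

log = logging.getLogger("rheokit")

LINEAR_PARAMS = ("movement", "velocity", "acceleration")
ANGULAR_PARAMS = ("body_angle", "resultant_length")

_SERIES_COLUMN = {"movement": "distance", "velocity": "velocity",
                  "acceleration": "acceleration"}


@dataclass
class RunConfig:
    """Fully serializable description of one analysis run."""

    out_dir: str = "rheokit_out"
    manifest: str | None = None      # CSV: trial_id, path, treatment, ...
    seed: int = 0
    bin_ms: float = 100.0
    likelihood_threshold: float = 0.6
    qc: bool = True
    movement_criterion: float = 0.7
    location_criterion: float = 1.5
    angle_band: float = 45.0
    min_bout: float = 0.1
    tail_amp_min: float = 0.3
    min_forward_translation: float = 0.0
    no_flow_mode: str = "orientation"
    period_bins: int = 10
    k_peaks: int = 3
    max_lag: int = 30
    roi_margin: float = 5.0
    cell_mm: float = 1.0
    control_group: str = "control"
    log_level: str = "INFO"
    # simulation block (used by `simulate`): group -> {profile fields}
    simulation: dict = field(default_factory=dict)
    n_per_group: int = 0
    fps: float = 60.0

    def config_hash(self) -> str:
        """Hash of the analytic configuration (where outputs go and how
        verbosely we log do not change what is computed)."""
        payload = asdict(self)
        payload.pop("out_dir", None)
        payload.pop("log_level", None)
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(raw) - known
        if bad:
            raise ConfigError(f"unknown config key(s): {sorted(bad)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def simulate_cohort(config: RunConfig) -> Path:
    """Write n tracks per group plus ground-truth sidecars and a manifest.

    Per-trial seeds are derived as ``seed + index`` so the manifest is
    reproducible from the base seed alone.
    """
    if config.n_per_group <= 0 and not config.simulation:
        raise ConfigError("simulation block and n_per_group are required")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    presets = preset_profiles()
    rows = []
    idx = 0
    schedule = StimulusSchedule()
    for group, spec_block in config.simulation.items():
        n = spec_block.get("n", config.n_per_group)
        if n <= 0:
            warnings.warn(f"group {group!r} has n=0 and is omitted", stacklevel=2)
            continue
        profile_name = spec_block.get("profile", group)
        base = presets.get(profile_name, SwimmerProfile())
        overrides = {k: v for k, v in spec_block.items()
                     if k in SwimmerProfile.__dataclass_fields__}
        profile = SwimmerProfile(**{**asdict(base), **overrides})
        treatment = spec_block.get("treatment", "custom")
        for i in range(n):
            trial = simulate_trial(
                profile,
                schedule=schedule,
                fps=config.fps,
                seed=config.seed + idx,
                trial_id=f"{group}_{i:03d}",
                treatment=treatment,
            )
            rows.append({**write_trial(trial, out), "group": group})
            idx += 1
    if not rows:
        raise ConfigError("no trials simulated: every group was empty")
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return out / "manifest.csv"


# ---------------------------------------------------------------------------
# per-trial processing


def process_trial(track, config: RunConfig,
                  schedule: StimulusSchedule | None = None) -> KinematicSeries:
    schedule = schedule or StimulusSchedule()
    if config.qc:
        track, _ = qc_track(track, config.movement_criterion,
                            config.location_criterion)
    binned = bin_track(track, schedule=schedule, bin_ms=config.bin_ms)
    return linear_series(binned)


def load_series(config: RunConfig) -> dict[str, list[KinematicSeries]]:
    """Read every manifest trial into a per-group list of kinematic series."""
    if not config.manifest:
        raise ConfigError("config.manifest is required for a run")
    mpath = Path(config.manifest)
    if not mpath.exists():
        raise ConfigError(f"manifest not found: {mpath}")
    manifest = pd.read_csv(mpath)
    if manifest.empty:
        raise ConfigError("manifest is empty")
    root = mpath.parent
    schedule = StimulusSchedule()
    groups: dict[str, list[KinematicSeries]] = {}
    for _, row in manifest.iterrows():
        try:
            track = read_pose_table(
                root / row["path"],
                trial_id=str(row["trial_id"]),
                treatment=str(row.get("treatment", "custom")),
                session=str(row.get("session", "")),
                fps=float(row["fps"]),
                px_per_mm=float(row["px_per_mm"]),
                likelihood_threshold=config.likelihood_threshold,
            )
            series = process_trial(track, config, schedule)
        except Exception as exc:
            raise DataError(
                f"stage=per-trial trial={row['trial_id']}: {exc}"
            ) from exc
        groups.setdefault(str(row.get("group", row.get("treatment", "all"))),
                          []).append(series)
    return groups


# ---------------------------------------------------------------------------
# group-level series


def group_mean_series(series_list, parameter: str) -> np.ndarray:
    """Across-fish group series per bin.

    Linear parameters: mean of within-fish mean-centered values ("relative"
    movement/velocity/acceleration).  body_angle: across-fish circular mean
    heading.  resultant_length: across-fish mean resultant length.
    Missing bins are excluded pairwise.
    """
    if parameter in LINEAR_PARAMS:
        mat = np.vstack([s.relative(_SERIES_COLUMN[parameter]) for s in series_list])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            return np.nanmean(mat, axis=0)
    h = np.vstack([np.radians(s.column("heading")) for s in series_list])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        c = np.nanmean(np.cos(h), axis=0)
        s_ = np.nanmean(np.sin(h), axis=0)
    if parameter == "body_angle":
        return np.degrees(np.arctan2(s_, c))
    if parameter == "resultant_length":
        return np.hypot(c, s_)
    raise ValueError(f"unknown parameter {parameter!r}")


def spectral_tables(groups, config: RunConfig):
    """Decompositions, spectra, dominant peaks and net shifts per group."""
    decomp_rows, spec_rows, peak_rows, shift_rows = [], [], [], []
    peaks_by = {}
    for group, series_list in groups.items():
        for parameter in LINEAR_PARAMS + ANGULAR_PARAMS:
            obs = group_mean_series(series_list, parameter)
            dec = decompose(obs, period=config.period_bins)
            bin_start = series_list[0].column("bin_start")
            decomp_rows.append(pd.DataFrame({
                "group": group, "parameter": parameter, "bin_start": bin_start,
                "observed": dec.observed, "trend": dec.trend,
                "periodic": dec.periodic, "noise": dec.noise,
            }))
            den = dec.denoised()
            den = den[np.isfinite(den)]
            ps = periodogram(den - den.mean())
            spec_rows.append(pd.DataFrame({
                "group": group, "parameter": parameter,
                "freq_hz": ps.freqs, "density": ps.density,
            }))
            pk = dominant_peaks(ps, k=config.k_peaks)
            peaks_by[(group, parameter)] = pk
            for rank, (f, d) in enumerate(pk.peaks, start=1):
                peak_rows.append({"group": group, "parameter": parameter,
                                  "rank": rank, "freq_hz": f, "density": d})
    ctl = config.control_group
    for (group, parameter), pk in peaks_by.items():
        if group == ctl or (ctl, parameter) not in peaks_by:
            continue
        ns = net_shift(pk, peaks_by[(ctl, parameter)])
        shift_rows.append({"group": group, "parameter": parameter,
                           "dfreq_hz": ns.dfreq, "ddensity": ns.ddensity,
                           "freq_label": ns.freq_label})
    return (
        pd.concat(decomp_rows, ignore_index=True),
        pd.concat(spec_rows, ignore_index=True),
        pd.DataFrame(peak_rows),
        pd.DataFrame(shift_rows),
    )


def correlogram_table(groups, config: RunConfig) -> pd.DataFrame:
    """Per-fish cross-correlograms averaged within group, one row per lag.

    Pairs: each relative linear series against the relative heading
    ("body_angle") and the absolute per-bin heading change
    ("heading_change").  Positive lag = angular change after linear change.
    """
    rows = []
    for group, series_list in groups.items():
        for lin_name in LINEAR_PARAMS:
            for ang_name in ("body_angle", "heading_change"):
                rs, cis = [], []
                for s in series_list:
                    a = s.relative(_SERIES_COLUMN[lin_name])
                    if ang_name == "body_angle":
                        b = s.column("heading")
                    else:
                        b = s.heading_change()
                    b = b - np.nanmean(b)
                    try:
                        cc = cross_correlate(a, b, max_lag=config.max_lag)
                    except DataError:
                        continue
                    rs.append(cc.r)
                    cis.append(cc.ci)
                if not rs:
                    continue
                r = np.nanmean(np.vstack(rs), axis=0)
                ci = float(np.mean(cis) / np.sqrt(len(rs)))
                lags = np.arange(-config.max_lag, config.max_lag + 1)
                strongest = int(lags[np.nanargmax(np.abs(r))])
                rows.append(pd.DataFrame({
                    "group": group, "pair": f"{lin_name}_x_{ang_name}",
                    "lag_bins": lags, "lag_s": lags * series_list[0].bin_s,
                    "r": r, "ci": ci, "strongest_lag": strongest,
                }))
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# full run


def run_pipeline(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Execute the full analysis and write the report bundle.

    Returns the bundle as a dict of DataFrames; also writes one CSV per
    table plus ``run_log.json`` into ``config.out_dir``.
    """
    logging.basicConfig(level=config.log_level)
    t0 = time.time()
    schedule = StimulusSchedule()
    groups = load_series(config)
    cfg_hash = config.config_hash()
    timings = {"load_s": round(time.time() - t0, 3)}

    bundle: dict[str, pd.DataFrame] = {}

    # --- orientation (per-fish mean angles, circular summaries, tests) ----
    ang_rows, summ_rows, test_rows = [], [], []
    for epoch in [ep.name for ep in schedule.epochs]:
        per_group_angles = {}
        for group, series_list in groups.items():
            ang = per_fish_means(series_list, epoch=epoch)
            ang = ang[np.isfinite(ang)]
            per_group_angles[group] = ang
            for a in ang:
                ang_rows.append({"group": group, "epoch": epoch, "mean_angle": a})
            if ang.size:
                cs = mean_resultant(ang)
                summ_rows.append({"group": group, "epoch": epoch, "n": cs.n,
                                  "theta": cs.theta, "rho": cs.rho,
                                  "angular_variance": cs.angular_variance})
                vt = v_test(ang, mu=0.0)
                test_rows.append({"test": "v_test", "groups": group,
                                  "epoch": epoch, "statistic": vt.statistic,
                                  "df": np.nan, "p": vt.p})
        usable = [a for a in per_group_angles.values() if a.size >= 2]
        if len(usable) >= 2:
            ww = watson_wheeler(*usable, rng=config.seed)
            test_rows.append({"test": "watson_wheeler",
                              "groups": "|".join(per_group_angles), "epoch": epoch,
                              "statistic": ww.statistic, "df": ww.df, "p": ww.p})
    bundle["per_fish_angles"] = pd.DataFrame(ang_rows)
    bundle["circular_summary"] = pd.DataFrame(summ_rows)
    bundle["circular_tests"] = pd.DataFrame(test_rows)
    timings["orientation_s"] = round(time.time() - t0, 3)

    # --- events -------------------------------------------------------------
    event_rows, summary_rows, curve_rows = [], [], []
    for group, series_list in groups.items():
        evs_by_trial = {}
        for s in series_list:
            evs = classify_events(
                s, angle_band=config.angle_band, min_bout=config.min_bout,
                tail_amp_min=config.tail_amp_min,
                min_forward_translation=config.min_forward_translation,
                no_flow_mode=config.no_flow_mode,
            )
            evs_by_trial[s.trial_id] = evs
            for ev in evs:
                event_rows.append({"group": group, "trial_id": s.trial_id,
                                   "start_s": ev.start, "end_s": ev.end,
                                   "duration_s": ev.duration,
                                   "mean_heading_deg": ev.mean_heading,
                                   "distance_mm": ev.distance})
            summ = summarize_events(evs, schedule, trial_id=s.trial_id)
            tab = summ.per_epoch.assign(group=group, trial_id=s.trial_id,
                                        latency_s=summ.latency)
            summary_rows.append(tab)
        curve = responder_curve(evs_by_trial, schedule, bin_s=config.bin_ms / 1000)
        curve_rows.append(curve.assign(group=group))
    bundle["events"] = pd.DataFrame(event_rows)
    bundle["event_summary"] = pd.concat(summary_rows, ignore_index=True)
    bundle["responder_curve"] = pd.concat(curve_rows, ignore_index=True)
    timings["events_s"] = round(time.time() - t0, 3)

    # --- spatial use --------------------------------------------------------
    roi_rows = []
    flow_epochs = tuple(ep.name for ep in schedule.flow_epochs())
    for group, series_list in groups.items():
        for window, epochs in [("no_flow", ("no_flow",)), ("flow", flow_epochs)]:
            for filt_name, filt in [("all", None), ("rheotaxis_band", (0.0, 45.0))]:
                occ = occupancy(series_list, angle_filter=filt, epochs=epochs,
                                roi_margin=config.roi_margin,
                                cell_mm=config.cell_mm,
                                arena=series_list[0].arena)
                row = {"group": group, "window": window, "filter": filt_name,
                       "n_bins": occ.n, "empty": occ.empty}
                row.update({f"frac_{k.lower()}": v
                            for k, v in occ.roi_fractions.items()})
                roi_rows.append(row)
    bundle["occupancy_roi"] = pd.DataFrame(roi_rows)
    timings["occupancy_s"] = round(time.time() - t0, 3)

    # --- spectral profile ---------------------------------------------------
    dec, spec, peaks, shifts = spectral_tables(groups, config)
    bundle["decomposition"] = dec
    bundle["spectra"] = spec
    bundle["dominant_peaks"] = peaks
    bundle["net_shift"] = shifts
    bundle["correlograms"] = correlogram_table(groups, config)
    timings["spectral_s"] = round(time.time() - t0, 3)

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, df in bundle.items():
        df = df.assign(config_hash=cfg_hash)
        df.to_csv(out / f"{name}.csv", index=False)
    run_log = {
        "package_version": __version__,
        "config_hash": cfg_hash,
        "seed": config.seed,
        "n_trials": {g: len(s) for g, s in groups.items()},
        "timings_s": timings,
        "config": asdict(config),
    }
    with open(out / "run_log.json", "w") as fh:
        json.dump(run_log, fh, indent=1, default=str)
    log.info("run complete: %s (%ss)", cfg_hash, timings["spectral_s"])
    return bundle


def external_dominant_frequency(
    data_dir, group: str = "neomycin", parameter: str = "movement",
    config: RunConfig | None = None,
) -> float:
    """Top dominant-peak frequency (Hz) of one group's movement-periodicity
    spectrum, computed from a locally provided pose-track export.

    ``data_dir`` must contain a ``manifest.csv`` naming per-trial pose
    tables (see :func:`load_series`).  Intended for the deposited study
    data, which is not distributed with this package.
    """
    config = config or RunConfig()
    config.manifest = str(Path(data_dir) / "manifest.csv")
    groups = load_series(config)
    if group not in groups:
        raise DataError(f"group {group!r} not present in {data_dir}")
    obs = group_mean_series(groups[group], parameter)
    dec = decompose(obs, period=config.period_bins)
    den = dec.denoised()
    den = den[np.isfinite(den)]
    pk = dominant_peaks(periodogram(den - den.mean()), k=1)
    if not pk.peaks:
        raise DataError("spectrum has no local maximum")
    return pk.peaks[0][0]
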