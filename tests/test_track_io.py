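"""Pose-table reading, calibration, QC outlier correction, and binning."""

import numpy as np
import pandas as pd
import pytest

from rheokit.core import (
    DataError,
    FormatError,
    ParameterError,
    ScheduleError,
    StimulusSchedule,
)
from rheokit.simulate import preset_profiles, scripted_track, simulate_trial
from rheokit.track_io import (
    bin_track,
    qc_track,
    read_pose_table,
    write_pose_table,
)

from conftest import wide_pose_csv


META = dict(trial_id="t", treatment="custom", fps=60.0, px_per_mm=10.0)


class TestReadPoseTable:
    def test_linear_calibration(self, tmp_path):
        path = wide_pose_csv(tmp_path / "p.csv", frames=3, px=100.0)
        track = read_pose_table(path, **META)
        assert track.n_frames == 3
        for kp in ("left_eye", "tail4"):
            assert np.allclose(track.xy(kp), 10.0)

    def test_calibration_is_pure_scale(self, tmp_path):
        path = wide_pose_csv(tmp_path / "p.csv", frames=3, px=120.0)
        base = read_pose_table(path, **META)
        scaled = read_pose_table(path, **{**META, "px_per_mm": 30.0})
        assert np.allclose(scaled.xy("swim_bladder") * 3.0,
                           base.xy("swim_bladder"))

    def test_missing_cells_become_nan_and_are_counted(self, tmp_path):
        path = wide_pose_csv(tmp_path / "p.csv", frames=3,
                             missing={(1, "swim_bladder")})
        track = read_pose_table(path, **META)
        assert np.isnan(track.xy("swim_bladder")[1]).all()
        assert np.isfinite(track.xy("swim_bladder")[[0, 2]]).all()
        assert track.fraction_missing() == pytest.approx(1 / 21)

    def test_missing_keypoint_column_names_it(self, tmp_path):
        path = wide_pose_csv(tmp_path / "p.csv", frames=2)
        raw = pd.read_csv(path, header=[0, 1, 2], index_col=0)
        raw = raw.drop(columns=[("scorer", "tail2", c)
                                for c in ("x", "y", "likelihood")])
        raw.to_csv(tmp_path / "bad.csv")
        with pytest.raises(FormatError, match="tail2"):
            read_pose_table(tmp_path / "bad.csv", **META)

    def test_non_monotone_frame_index(self, tmp_path):
        path = wide_pose_csv(tmp_path / "p.csv", frames=3)
        raw = pd.read_csv(path, header=[0, 1, 2], index_col=0)
        raw.index = [0, 2, 1]
        raw.to_csv(tmp_path / "bad.csv")
        with pytest.raises(DataError):
            read_pose_table(tmp_path / "bad.csv", **META)

    def test_bad_calibration(self, tmp_path):
        path = wide_pose_csv(tmp_path / "p.csv", frames=2)
        with pytest.raises(ParameterError):
            read_pose_table(path, **{**META, "px_per_mm": 0.0})

    @pytest.mark.parametrize("dialect", ["wide", "long"])
    def test_round_trip(self, tmp_path, dialect):
        trial = simulate_trial(preset_profiles()["control_like"], fps=60,
                               seed=3, trial_id="rt", treatment="control")
        path = write_pose_table(trial.track, tmp_path / "rt.csv",
                                dialect=dialect)
        back = read_pose_table(path, trial_id="rt", treatment="control",
                               fps=60.0, px_per_mm=trial.track.px_per_mm)
        for kp in ("swim_bladder", "left_eye", "tail4"):
            a, b = trial.track.xy(kp), back.xy(kp)
            m = np.isfinite(a).all(axis=1)
            assert (np.isfinite(b).all(axis=1) == m).all()
            assert np.nanmax(np.abs(a[m] - b[m])) < 1e-9


class TestQC:
    def _clean_track(self, n=50):
        sb = np.tile([15.0, 15.0], (n, 1))
        return scripted_track(sb, np.zeros(n))

    def test_clean_track_untouched(self):
        track = self._clean_track()
        out, report = qc_track(track)
        assert report.n_frames_flagged_outlier == 0
        assert report.corrections_applied == []
        pd.testing.assert_frame_equal(out.data, track.data)

    def test_planted_teleport_flagged_and_held(self):
        track = self._clean_track()
        bl = 0.8 + 0.7 * 4  # eye-mid to tail4 with this rig geometry
        track.data.loc[20, ("swim_bladder", "x")] = 15.0 + 10 * bl
        out, report = qc_track(track)
        assert [(f, kp) for f, kp, _ in report.corrections_applied] == [
            (20, "swim_bladder")
        ]
        assert out.data.loc[20, ("swim_bladder", "x")] == pytest.approx(15.0)
        # every other sample untouched
        others = out.data.drop(index=20)
        pd.testing.assert_frame_equal(others, track.data.drop(index=20))

    def test_idempotent(self):
        track = self._clean_track()
        track.data.loc[10, ("tail3", "y")] = 40.0
        once, r1 = qc_track(track)
        twice, r2 = qc_track(once)
        assert r1.n_frames_flagged_outlier >= 1
        assert r2.corrections_applied == []
        pd.testing.assert_frame_equal(twice.data, once.data)

    def test_excess_missing_warns(self):
        track = self._clean_track(n=100)
        for f in range(5):
            for kp in ("swim_bladder",):
                track.data.loc[f * 2, (kp, "x")] = np.nan
                track.data.loc[f * 2, (kp, "y")] = np.nan
        # 5 missing samples of 700 -> 0.71%: no warning expected yet
        miss = {(f, "tail1") for f in range(40)}
        for f, kp in miss:
            track.data.loc[f, (kp, "x")] = np.nan
            track.data.loc[f, (kp, "y")] = np.nan
        with pytest.warns(UserWarning, match="missing"):
            _, report = qc_track(track)
        assert report.fraction_missing == pytest.approx(45 / 700)

    def test_too_few_frames(self):
        track = self._clean_track(n=1)
        with pytest.raises(DataError):
            qc_track(track)


class TestBinning:
    @pytest.mark.parametrize("fps,fpb", [(200.0, 20), (60.0, 6)])
    def test_bin_counts_and_epochs(self, fps, fpb, schedule):
        n = int(30 * fps)
        sb = np.tile([15.0, 15.0], (n, 1))
        track = scripted_track(sb, np.zeros(n), fps=fps)
        binned = bin_track(track, schedule)
        assert binned.n_bins == 300
        assert (binned.n_valid["swim_bladder"] == fpb).all()
        assert (binned.epoch == "no_flow").sum() == 100
        assert (binned.epoch == "initial_flow").sum() == 100

    def test_bin_mean_position(self, schedule):
        n = 30 * 60
        x = np.full(n, 15.0)
        x[:6] = [1, 1, 2, 2, 3, 3]  # first bin holds x = 1, 2, 3 mm
        sb = np.stack([x, np.full(n, 15.0)], axis=1)
        track = scripted_track(sb, np.zeros(n), fps=60.0)
        binned = bin_track(track, schedule)
        assert binned.bin_xy("swim_bladder")[0, 0] == pytest.approx(2.0)

    def test_constant_track_bins_to_constant(self, schedule):
        n = 30 * 60
        sb = np.tile([12.0, 18.0], (n, 1))
        binned = bin_track(scripted_track(sb, np.zeros(n)), schedule)
        assert np.allclose(binned.bin_xy("swim_bladder"), [12.0, 18.0])

    def test_bin_width_must_divide_frame_period(self, schedule):
        n = 30 * 60
        sb = np.tile([15.0, 15.0], (n, 1))
        track = scripted_track(sb, np.zeros(n))
        with pytest.raises(ParameterError):
            bin_track(track, schedule, bin_ms=110.0)

    def test_schedule_must_cover_track(self):
        n = 40 * 60
        sb = np.tile([15.0, 15.0], (n, 1))
        track = scripted_track(sb, np.zeros(n))
        with pytest.raises(ScheduleError):
            bin_track(track, StimulusSchedule())
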