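"""Rheotaxis event classification, epoch summaries, responder curves."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rheokit.core import ParameterError, StimulusSchedule
from rheokit.events import (
    RheotaxisEvent,
    classify_events,
    responder_curve,
    split_at_epochs,
    summarize_events,
)
from rheokit.kinematics import linear_series
from rheokit.track_io import bin_track

from conftest import drift_track, swimming_track


def _series(track, schedule=None):
    return linear_series(bin_track(track, schedule or StimulusSchedule()))


def _flow_window(fps=60.0, start=12.0, stop=17.0):
    n = int(30 * fps)
    t = np.arange(n) / fps
    return (t >= start) & (t < stop)


class TestClassifier:
    def test_compliant_bout_is_one_event(self):
        s = _series(swimming_track(_flow_window()))
        evs = [e for e in classify_events(s) if e.end > 10.0]
        assert len(evs) == 1
        assert evs[0].duration == pytest.approx(5.0)
        assert abs(evs[0].mean_heading) <= 45.0

    def test_bad_orientation_never_classifies(self):
        s = _series(swimming_track(_flow_window(), heading_in=60.0))
        assert classify_events(s) == []

    def test_passive_drift_at_zero_heading_never_classifies(self):
        s = _series(drift_track())
        assert [e for e in classify_events(s) if e.end > 10.0] == []

    def test_sub_bout_below_100_ms_is_dropped(self):
        # 90 ms of compliance at 200 fps, straddling a bin boundary: no
        # analysis bin is majority-compliant, so no event can reach 100 ms
        s = _series(swimming_track(_flow_window(fps=200.0, start=12.055,
                                                stop=12.145), fps=200.0))
        assert [e for e in classify_events(s) if e.end > 10.0] == []

    def test_single_full_bin_is_an_event(self):
        s = _series(swimming_track(_flow_window(start=12.0, stop=12.1)))
        evs = [e for e in classify_events(s) if e.end > 10.0]
        assert len(evs) == 1
        assert evs[0].duration == pytest.approx(0.1)

    def test_missing_bin_breaks_a_run(self):
        s = _series(swimming_track(_flow_window()))
        s.df.loc[s.df["bin_start"].sub(14.0).abs().lt(1e-9), "valid"] = False
        evs = [e for e in classify_events(s) if e.end > 10.0]
        assert len(evs) == 2

    def test_parameter_validation(self):
        s = _series(swimming_track(_flow_window()))
        with pytest.raises(ParameterError):
            classify_events(s, min_bout=0.0)
        with pytest.raises(ParameterError):
            classify_events(s, angle_band=-1.0)

    def test_events_are_disjoint_and_ordered(self):
        rng = np.random.default_rng(0)
        mask = rng.random(1800) < 0.4
        s = _series(swimming_track(mask))
        evs = classify_events(s)
        for a, b in zip(evs, evs[1:]):
            assert a.end <= b.start + 1e-12

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_loosening_criteria_is_monotone(self, seed):
        rng = np.random.default_rng(seed)
        blocks = rng.random(100) < 0.5
        mask = np.repeat(blocks, 18)
        s = _series(swimming_track(mask, heading_in=float(rng.uniform(0, 80))))
        n_tight = len(classify_events(s, angle_band=30.0, min_bout=0.3))
        n_wide = len(classify_events(s, angle_band=60.0, min_bout=0.3))
        n_short = len(classify_events(s, angle_band=30.0, min_bout=0.1))
        assert n_wide >= n_tight
        assert n_short >= n_tight


class TestSummaries:
    def test_arithmetic_of_means(self, schedule):
        evs = [
            RheotaxisEvent("t", 11.0, 13.0, 5.0, 8.0, ("initial_flow",)),
            RheotaxisEvent("t", 14.0, 18.0, -3.0, 12.0, ("initial_flow",)),
        ]
        summ = summarize_events(evs, schedule)
        row = summ.per_epoch.set_index("epoch").loc["initial_flow"]
        assert row["n_events"] == 2
        assert row["mean_duration"] == pytest.approx(3.0)
        assert row["total_distance"] == pytest.approx(20.0)

    def test_latency_is_measured_from_flow_onset(self, schedule):
        evs = [RheotaxisEvent("t", 12.4, 13.0, 0.0, 1.0, ("initial_flow",))]
        assert summarize_events(evs, schedule).latency == pytest.approx(2.4)
        assert np.isnan(summarize_events([], schedule).latency)

    def test_boundary_event_split_conserves_duration_and_distance(self, schedule):
        ev = RheotaxisEvent("t", 19.5, 20.5, 0.0, 4.0,
                            ("initial_flow", "final_flow"))
        pieces = split_at_epochs(ev, schedule)
        assert [p[0] for p in pieces] == ["initial_flow", "final_flow"]
        assert sum(hi - lo for _, lo, hi, _ in pieces) == pytest.approx(1.0)
        assert sum(p[3] for p in pieces) == pytest.approx(4.0)
        summ = summarize_events([ev], schedule)
        tab = summ.per_epoch.set_index("epoch")
        assert tab.loc["initial_flow", "n_events"] == 1
        assert tab.loc["final_flow", "n_events"] == 1
        assert tab.loc["initial_flow", "mean_duration"] == pytest.approx(0.5)


class TestResponderCurve:
    def test_immediate_universal_response(self, schedule):
        evs = {f"f{i}": [RheotaxisEvent(f"f{i}", 10.0, 12.0, 0, 1,
                                        ("initial_flow",))]
               for i in range(5)}
        curve = responder_curve(evs, schedule)
        assert np.allclose(curve["proportion"], 1.0)

    def test_no_response_at_all(self, schedule):
        curve = responder_curve({f"f{i}": [] for i in range(5)}, schedule)
        assert np.allclose(curve["proportion"], 0.0)

    def test_staggered_first_events_step_by_tenths(self, schedule):
        evs = {}
        for i, t0 in enumerate(np.arange(11.0, 21.0)):
            evs[f"f{i}"] = [RheotaxisEvent(f"f{i}", t0, t0 + 0.5, 0, 1, ())]
        curve = responder_curve(evs, schedule)
        t = curve["t"].to_numpy()
        # direct enumeration: by 11 s one fish of ten has responded, etc.
        for k, t0 in enumerate(np.arange(11.0, 20.0), start=1):
            i = int(np.argmin(np.abs(t - t0)))
            assert curve["proportion"].iloc[i] == pytest.approx(k / 10)
        assert curve["proportion"].is_monotonic_increasing
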