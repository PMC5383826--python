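"""Glance detection against dynamic AOIs, exclusions and summaries."""

import numpy as np
import pandas as pd
import pytest

from sagame.gaze import (AOITrack, GazeParams, GazeQuality, apply_exclusions,
                         detect_glances, effective_rate,
                         participant_gaze_summary, summaries_to_frame)


def static_track(appear=0.0, end=10.0, cx=0.3, cy=0.3, r=0.08):
    return AOITrack(clip_id="c", target_id="t", appear_time=appear,
                    end_time=end, t=np.array([appear, end]),
                    x=np.array([cx, cx]), y=np.array([cy, cy]),
                    radius=np.array([r, r]))


def stream(t, inside, track, valid=None):
    """Samples at times t; inside=True puts the sample at the AOI center."""
    inside = np.asarray(inside, dtype=bool)
    x = np.where(inside, track.x[0], 0.9)
    y = np.where(inside, track.y[0], 0.9)
    return pd.DataFrame({"t_s": t, "x": x, "y": y,
                         "valid": np.ones(len(t), bool) if valid is None else valid})


def test_single_run_detected_with_correct_dwell():
    # 400 ms inside the AOI sampled at 20 Hz
    track = static_track()
    t = np.arange(0, 5, 0.05)
    inside = (t >= 1.0) & (t <= 1.4)
    events = detect_glances(stream(t, inside, track), track)
    assert len(events) == 1
    assert events[0].dwell == pytest.approx(0.40, abs=0.05 + 1e-9)
    assert events[0].onset == pytest.approx(1.0, abs=0.05)


def test_all_outside_yields_nothing():
    track = static_track()
    t = np.arange(0, 5, 0.05)
    assert detect_glances(stream(t, np.zeros(len(t), bool), track), track) == []
    assert detect_glances(stream(np.array([]), [], track), track) == []


def test_short_gap_merges_runs():
    # 40 Hz sampling; two runs split by a 50 ms out-of-AOI gap are one glance
    track = static_track()
    t = np.arange(0, 5, 0.025)
    inside = ((t >= 1.0) & (t < 1.2)) | ((t > 1.225) & (t <= 1.5))
    events = detect_glances(stream(t, inside, track), track)
    assert len(events) == 1  # 50 ms gap <= 75 ms merge threshold
    assert events[0].dwell == pytest.approx(0.5, abs=0.06)


def test_long_gap_keeps_runs_separate():
    track = static_track()
    t = np.arange(0, 5, 0.05)
    inside = ((t >= 1.0) & (t <= 1.3)) | ((t >= 2.0) & (t <= 2.3))
    events = detect_glances(stream(t, inside, track), track)
    assert len(events) == 2


def test_sub_minimum_runs_dropped():
    track = static_track()
    t = np.arange(0, 5, 0.05)
    inside = (t >= 1.0) & (t <= 1.05)  # 50 ms < 100 ms minimum
    assert detect_glances(stream(t, inside, track), track) == []


def test_samples_outside_track_window_ignored():
    track = static_track(appear=2.0, end=4.0)
    t = np.arange(0, 6, 0.05)
    inside = (t >= 0.5) & (t <= 1.5)  # before the target appears
    assert detect_glances(stream(t, inside, track), track) == []


def test_invalid_samples_break_runs_but_count_as_gap():
    track = static_track()
    t = np.arange(0, 5, 0.05)
    inside = (t >= 1.0) & (t <= 1.4)
    valid = np.ones(len(t), bool)
    valid[np.argmin(np.abs(t - 1.2))] = False  # 100 ms hole: two runs merged
    events = detect_glances(stream(t, inside, track, valid), track)
    assert len(events) == 2  # gap is 2 sample periods = 100 ms > 75 ms
    # with a larger merge tolerance the hole is bridged
    events = detect_glances(stream(t, inside, track, valid), track,
                            GazeParams(max_gap=0.12))
    assert len(events) == 1


def test_dwell_conservation(bank, tracks, small_cohort):
    for s in small_cohort[:4]:
        for tid, tr in tracks.items():
            events = detect_glances(s.gaze[tr.clip_id], tr)
            assert sum(e.dwell for e in events) <= tr.end_time - tr.appear_time


def test_effective_rate():
    assert effective_rate(np.arange(0, 1.01, 0.1)) == pytest.approx(10.0)
    assert effective_rate(np.array([0.0])) == 0.0


def test_exclusion_rules_and_idempotence():
    fast = pd.DataFrame({"t_s": np.arange(0, 5, 0.05), "x": 0.5, "y": 0.5,
                         "valid": True})
    slow = pd.DataFrame({"t_s": np.arange(0, 5, 0.21), "x": 0.5, "y": 0.5,
                         "valid": True})
    streams = {"good": {"c1": fast, "c2": slow},
               "bad_cal": {"c1": fast},
               "flagged": {"c1": fast}}
    qualities = [
        GazeQuality("good", calibration_error=1.0),
        GazeQuality("bad_cal", calibration_error=2.1),
        GazeQuality("flagged", calibration_error=0.5, manually_flagged=True),
    ]
    retained, log = apply_exclusions(qualities, streams)
    assert set(retained) == {"good"}
    assert set(retained["good"]) == {"c1"}  # slow clip dropped (< 5 Hz)
    reasons = {entry[1]: entry[2] for entry in log}
    assert "calibration" in reasons["bad_cal"]
    assert "visual inspection" in reasons["flagged"]
    assert "Hz" in reasons["good/c2"]
    # idempotence
    again, log2 = apply_exclusions([qualities[0]], retained)
    assert again == retained
    assert log2 == []


def test_clean_data_not_excluded():
    fast = pd.DataFrame({"t_s": np.arange(0, 5, 0.05), "x": 0.5, "y": 0.5,
                         "valid": True})
    retained, log = apply_exclusions([GazeQuality("p", 0.5)], {"p": {"c": fast}})
    assert log == [] and set(retained["p"]) == {"c"}


def test_summary_counts_looked_targets():
    tracks = {f"t{i}": static_track() for i in range(10)}
    events = {tid: [] for tid in tracks}
    from sagame.gaze import GlanceEvent

    for i in range(5):
        events[f"t{i}"] = [GlanceEvent(f"t{i}", 1.0, 1.5),
                           GlanceEvent(f"t{i}", 3.0, 3.2)]
    s = participant_gaze_summary(events, tracks, "p")
    assert s.pct_targets_looked == 50.0
    assert s.avg_glance_freq == pytest.approx(2.0)
    assert s.avg_first_glance_latency == pytest.approx(1.0)
    assert s.avg_dwell_time == pytest.approx(0.7)


def test_summary_with_no_glances():
    tracks = {"t0": static_track(), "t1": static_track()}
    s = participant_gaze_summary({"t0": [], "t1": []}, tracks, "p")
    assert s.pct_targets_looked == 0.0
    assert s.avg_glance_freq is None
    assert s.avg_first_glance_latency is None
    assert s.avg_dwell_time is None
    df = summaries_to_frame([s])
    assert df["avg_dwell_time"].isna().all()
    with pytest.raises(ValueError, match="unusable"):
        participant_gaze_summary({}, tracks, "p")


def test_p_look_recovery():
    # fraction of targets with a detected glance tracks the generative p_look
    import dataclasses

    from sagame.observer import ADULT_PROFILE, simulate_gaze

    looked = 0
    n = 300
    track = static_track(end=8.0)
    from sagame.bank import ClipSpec, LocationSpec

    clip = ClipSpec(clip_id="c", role="game", duration=8.0, mask_time=8.0,
                    locations=(LocationSpec("c", "t", "overt", 0.3, 0.3, 0.08),
                               LocationSpec("c", "e", "empty", 0.7, 0.7, 0.08)))
    profile = dataclasses.replace(ADULT_PROFILE, p_look=0.55)
    for seed in range(n):
        samples, _ = simulate_gaze(profile, clip, track, seed=seed)
        if detect_glances(samples, track):
            looked += 1
    assert looked / n == pytest.approx(0.55, abs=0.06)
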