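"""Dynamic area-of-interest (AOI) gaze analysis.

Glances toward hazard targets are detected from raw gaze sample streams
against circular AOIs that move with the target from the moment it first
becomes identifiable until the video is masked.  Per participant, four
summary statistics are computed over the set of analysed targets:

* percentage of targets looked toward at least once,
* average glance frequency per looked-at target,
* average first-glance latency from target appearance (seconds),
* average total dwell time per looked-at target (seconds).

A glance is a maximal run of valid in-AOI samples lasting at least
``min_glance`` seconds; runs separated by gaps of at most ``max_gap`` seconds
are merged (invalid samples break runs but count toward gap duration).

Participant- and clip-level quality exclusions mirror standard mobile
eye-tracking practice: a participant is dropped when the mean calibration
error over a nine-point accuracy test exceeds 2 degrees, and a clip is
dropped when its effective sample rate falls below 5 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class AOITrack:
    """Circular AOI keyframes for one target within one clip.

    Keyframe arrays are sampled at video rate (or sparser); circle center and
    radius are linearly interpolated between keyframes.
    """

    clip_id: str
    target_id: str
    appear_time: float  # first moment the target is identifiable
    end_time: float  # mask onset
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    radius: np.ndarray

    def circle_at(self, times: np.ndarray):
        cx = np.interp(times, self.t, self.x)
        cy = np.interp(times, self.t, self.y)
        r = np.interp(times, self.t, self.radius)
        return cx, cy, r


@dataclass(frozen=True)
class GlanceEvent:
    target_id: str
    onset: float
    offset: float

    @property
    def dwell(self) -> float:
        return self.offset - self.onset


@dataclass(frozen=True)
class GazeQuality:
    participant_id: str
    calibration_error: float  # degrees, mean over a nine-point test
    clip_rates: Mapping[str, float] = field(default_factory=dict)  # Hz
    manually_flagged: bool = False  # visual-inspection exclusion flag


@dataclass(frozen=True)
class GazeParams:
    min_glance: float = 0.100  # seconds
    max_gap: float = 0.075  # seconds
    calibration_cutoff: float = 2.0  # degrees
    min_rate: float = 5.0  # Hz


@dataclass(frozen=True)
class GazeSummary:
    participant_id: str
    n_targets: int
    n_looked: int
    pct_targets_looked: float  # percent
    avg_glance_freq: float | None  # glances per looked-at target
    avg_first_glance_latency: float | None  # s from target appearance
    avg_dwell_time: float | None  # s per looked-at target


def effective_rate(t: np.ndarray) -> float:
    """Effective sample rate of a stream: (n-1) / (t_last - t_first)."""
    t = np.asarray(t, dtype=float)
    if len(t) < 2 or t[-1] <= t[0]:
        return 0.0
    return (len(t) - 1) / (t[-1] - t[0])


def detect_glances(samples: pd.DataFrame, track: AOITrack,
                   params: GazeParams | None = None) -> list[GlanceEvent]:
    """Detect glances into a dynamic AOI.

    ``samples`` needs columns ``t_s``, ``x``, ``y`` and optionally ``valid``.
    Samples before the target appears or after the mask are ignored.
    """
    p = params or GazeParams()
    if len(samples) == 0:
        return []
    t = samples["t_s"].to_numpy(dtype=float)
    keep = (t >= track.appear_time) & (t <= track.end_time)
    if not keep.any():
        return []
    t = t[keep]
    x = samples["x"].to_numpy(dtype=float)[keep]
    y = samples["y"].to_numpy(dtype=float)[keep]
    valid = (samples["valid"].to_numpy(dtype=bool)[keep]
             if "valid" in samples.columns else np.ones(len(t), dtype=bool))

    cx, cy, r = track.circle_at(t)
    inside = valid & ((x - cx) ** 2 + (y - cy) ** 2 <= r**2)
    if not inside.any():
        return []

    # maximal runs of in-AOI samples
    idx = np.flatnonzero(inside)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([idx[0]], idx[breaks + 1]))
    ends = np.concatenate((idx[breaks], [idx[-1]]))
    runs = [(t[s], t[e]) for s, e in zip(starts, ends)]

    # merge runs separated by short gaps (invalid samples count as gap time)
    merged = [list(runs[0])]
    for on, off in runs[1:]:
        if on - merged[-1][1] <= p.max_gap:
            merged[-1][1] = off
        else:
            merged.append([on, off])

    return [GlanceEvent(track.target_id, on, off)
            for on, off in merged if off - on >= p.min_glance]


def apply_exclusions(qualities: Iterable[GazeQuality],
                     streams: Mapping[str, Mapping[str, pd.DataFrame]],
                     params: GazeParams | None = None):
    """Apply participant- and clip-level gaze quality exclusions.

    ``streams`` maps participant_id -> clip_id -> sample table.  Returns
    ``(retained, log)`` where ``log`` is a list of (level, id, reason) rows.
    Exclusion is idempotent: re-applying it to the retained set is a no-op.
    """
    p = params or GazeParams()
    qual = {q.participant_id: q for q in qualities}
    retained: dict[str, dict[str, pd.DataFrame]] = {}
    log: list[tuple[str, str, str]] = []
    for pid, clips in streams.items():
        q = qual.get(pid)
        if q is None:
            log.append(("participant", pid, "no quality record"))
            continue
        if q.calibration_error > p.calibration_cutoff:
            log.append(("participant", pid,
                        f"calibration error {q.calibration_error:.2f} deg > "
                        f"{p.calibration_cutoff} deg"))
            continue
        if q.manually_flagged:
            log.append(("participant", pid, "flagged on visual inspection"))
            continue
        kept = {}
        for clip_id, df in clips.items():
            rate = q.clip_rates.get(clip_id, effective_rate(df["t_s"].to_numpy()))
            if rate < p.min_rate:
                log.append(("clip", f"{pid}/{clip_id}",
                            f"effective rate {rate:.1f} Hz < {p.min_rate} Hz"))
                continue
            kept[clip_id] = df
        retained[pid] = kept
    return retained, log


def participant_gaze_summary(events_by_target: Mapping[str, Sequence[GlanceEvent]],
                             tracks: Mapping[str, AOITrack],
                             participant_id: str = "") -> GazeSummary:
    """Summarize glances over the analysed targets for one participant.

    ``events_by_target`` must have one entry per retained target (possibly an
    empty list).  Frequency, latency and dwell are averaged over looked-at
    targets only; they are ``None`` when no target was looked at.
    """
    if not events_by_target:
        raise ValueError("no retained targets: participant unusable")
    n = len(events_by_target)
    freqs, latencies, dwells = [], [], []
    for tid, events in events_by_target.items():
        if not events:
            continue
        track = tracks[tid]
        freqs.append(len(events))
        latencies.append(min(e.onset for e in events) - track.appear_time)
        dwells.append(sum(e.dwell for e in events))
    looked = len(freqs)
    return GazeSummary(
        participant_id=participant_id,
        n_targets=n,
        n_looked=looked,
        pct_targets_looked=100.0 * looked / n,
        avg_glance_freq=float(np.mean(freqs)) if looked else None,
        avg_first_glance_latency=float(np.mean(latencies)) if looked else None,
        avg_dwell_time=float(np.mean(dwells)) if looked else None,
    )


def summaries_to_frame(summaries: Iterable[GazeSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"participant_id": s.participant_id,
          "pct_targets_looked": s.pct_targets_looked,
          "avg_glance_freq": s.avg_glance_freq,
          "avg_first_glance_latency": s.avg_first_glance_latency,
          "avg_dwell_time": s.avg_dwell_time} for s in summaries]
    )


def gaze_accuracy_regression(summaries: pd.DataFrame,
                             logit_accuracy: pd.Series) -> dict:
    """Simple linear regression of logit-accuracy on each gaze parameter.

    Returns one :class:`~sagame.stats.RegressionResult` per parameter;
    participants missing a parameter (never looked) are dropped pairwise.
    """
    from .stats import ols_regression

    out = {}
    for col in ("pct_targets_looked", "avg_glance_freq",
                "avg_first_glance_latency", "avg_dwell_time"):
        x = summaries[col].astype(float)
        mask = x.notna() & logit_accuracy.notna()
        if mask.sum() < 3:
            raise ValueError(f"fewer than 3 usable participants for {col}")
        out[col] = ols_regression(logit_accuracy[mask].to_numpy(),
                                  x[mask].to_numpy()[:, None],
                                  names=[col])
    return out


# ---------------------------------------------------------------------------
# AOI track construction and serialization

def make_aoi_tracks(bank, n_targets: int = 10, seed: int = 0,
                    visible_window: float = 6.0,
                    min_offcenter: float = 0.15) -> dict[str, AOITrack]:
    """Build analysed AOI tracks from a stimulus bank.

    Picks overt-target locations in distinct game clips, preferring locations
    away from the screen center (so glances are distinguishable from looking
    in the direction of movement).  Each track runs from ``appear_time =
    max(0, mask_time - visible_window)`` to the mask, with a small linear
    drift of the circle center.
    """
    from ._rng import rng_for

    rng = rng_for(seed, "aoi")
    candidates = []
    for c in bank.game_clips:
        overt = [l for l in c.locations if l.kind == "overt"]
        if not overt:
            continue
        # prefer the most off-center overt location of the clip
        loc = max(overt, key=lambda l: (l.x - 0.5) ** 2 + (l.y - 0.5) ** 2)
        dist = np.hypot(loc.x - 0.5, loc.y - 0.5)
        if dist >= min_offcenter:
            candidates.append((dist, c, loc))
    candidates.sort(key=lambda z: -z[0])
    if len(candidates) < n_targets:
        raise ValueError(f"only {len(candidates)} off-center overt targets "
                         f"available, need {n_targets}")
    tracks = {}
    for dist, c, loc in candidates[:n_targets]:
        appear = max(0.0, c.mask_time - visible_window)
        drift = rng.uniform(-0.02, 0.02, size=2)
        t = np.array([appear, c.mask_time])
        tracks[loc.location_id] = AOITrack(
            clip_id=c.clip_id, target_id=loc.location_id,
            appear_time=appear, end_time=c.mask_time,
            t=t, x=np.array([loc.x, loc.x + drift[0]]),
            y=np.array([loc.y, loc.y + drift[1]]),
            radius=np.array([loc.radius, loc.radius]))
    return tracks


def tracks_to_frame(tracks: Mapping[str, AOITrack]) -> pd.DataFrame:
    rows = []
    for tr in tracks.values():
        for i in range(len(tr.t)):
            rows.append({"clip_id": tr.clip_id, "target_id": tr.target_id,
                         "appear_time_s": tr.appear_time,
                         "end_time_s": tr.end_time, "t_s": tr.t[i],
                         "x": tr.x[i], "y": tr.y[i], "radius": tr.radius[i]})
    return pd.DataFrame(rows)


def tracks_from_frame(df: pd.DataFrame) -> dict[str, AOITrack]:
    tracks = {}
    for tid, g in df.groupby("target_id", sort=False):
        g = g.sort_values("t_s")
        tracks[str(tid)] = AOITrack(
            clip_id=str(g.iloc[0]["clip_id"]), target_id=str(tid),
            appear_time=float(g.iloc[0]["appear_time_s"]),
            end_time=float(g.iloc[0]["end_time_s"]),
            t=g["t_s"].to_numpy(float), x=g["x"].to_numpy(float),
            y=g["y"].to_numpy(float), radius=g["radius"].to_numpy(float))
    return tracks
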