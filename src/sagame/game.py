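"""Game scoring: points, feedback labels, running total and phase partition.

Scoring follows the game's fixed point schedule: selecting a location with a
target gains 5 points (hit), failing to select one loses 5 (miss), correctly
leaving an empty location unselected gains 1 (correct rejection), and
selecting an empty location is worth 0 (false alarm).  The on-screen running
total is clamped at zero after every clip.  The asymmetric schedule rewards
detecting targets while signalling that it is never wrong to "play it safe",
but still pays for rejecting empty locations so that selecting everything is
not optimal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .bank import ClipSpec, StimulusBank
from .observer import ResponseRecord

POINTS = {"hit": 5, "miss": -5, "correct_rejection": 1, "false_alarm": 0}

FEEDBACK = {"hit": "detected", "miss": "missed",
            "correct_rejection": "empty_correct", "false_alarm": "empty_selected"}


@dataclass(frozen=True)
class ScoreEvent:
    participant_id: str
    clip_id: str
    location_id: str
    outcome: str  # hit | miss | correct_rejection | false_alarm
    points_delta: int
    feedback_label: str
    view_blocker_note: bool = False  # covert targets get an extra note


@dataclass(frozen=True)
class ScoreBoard:
    running_total: tuple[int, ...]  # after each clip, clamped at zero
    final_points: int
    unclamped_final: int


def classify(target_present: bool, selected: bool) -> str:
    if target_present:
        return "hit" if selected else "miss"
    return "false_alarm" if selected else "correct_rejection"


def score_clip(responses: Sequence[ResponseRecord], clip: ClipSpec) -> list[ScoreEvent]:
    """Score one clip's responses; one event per location."""
    by_loc = {r.location_id: r for r in responses}
    clip_locs = {l.location_id: l for l in clip.locations}
    missing = set(clip_locs) - set(by_loc)
    extra = set(by_loc) - set(clip_locs)
    if missing or extra:
        raise ValueError(
            f"{clip.clip_id}: responses do not cover the clip's locations "
            f"(missing={sorted(missing)}, extra={sorted(extra)})")
    events = []
    for loc_id, loc in clip_locs.items():
        r = by_loc[loc_id]
        if r.target_present != loc.has_target:
            raise ValueError(f"{loc_id}: response ground truth disagrees with clip")
        outcome = classify(r.target_present, r.selected)
        events.append(ScoreEvent(
            participant_id=r.participant_id, clip_id=clip.clip_id,
            location_id=loc_id, outcome=outcome,
            points_delta=POINTS[outcome], feedback_label=FEEDBACK[outcome],
            view_blocker_note=(loc.kind == "covert" and outcome in ("hit", "miss")),
        ))
    return events


def accumulate_points(clip_deltas: Sequence[int]) -> ScoreBoard:
    """Running total over clips in presentation order, clamped at zero."""
    totals = []
    total = 0
    unclamped = 0
    for delta in clip_deltas:
        unclamped += delta
        total = max(0, total + delta)
        totals.append(total)
    return ScoreBoard(running_total=tuple(totals), final_points=total,
                      unclamped_final=unclamped)


def score_session(session, bank: StimulusBank) -> tuple[list[ScoreEvent], ScoreBoard]:
    """Score a whole session in presentation order."""
    by_clip: dict[str, list[ResponseRecord]] = {}
    for r in session.responses:
        by_clip.setdefault(r.clip_id, []).append(r)
    events: list[ScoreEvent] = []
    deltas = []
    for clip_id in session.order:
        ev = score_clip(by_clip[clip_id], bank.clip(clip_id))
        events.extend(ev)
        deltas.append(sum(e.points_delta for e in ev))
    return events, accumulate_points(deltas)


def game_points(session, bank: StimulusBank) -> int:
    """Final clamped points over game clips only (practice still played)."""
    _, board = score_session(session, bank)
    return board.final_points


def partition_phases(order: Sequence[str],
                     practice_ids: Iterable[str] = ()) -> dict[str, str]:
    """Map the 30 game clips of an order to start / middle / end phases.

    Practice clips are excluded before partitioning.  Raises when the number
    of remaining game clips is not exactly 30.
    """
    practice = set(practice_ids)
    game = [c for c in order if c not in practice]
    if len(game) != 30:
        raise ValueError(f"expected exactly 30 game clips, found {len(game)}")
    labels = {}
    names = ("start", "middle", "end")
    for pos, clip_id in enumerate(game):
        labels[clip_id] = names[pos // 10]
    return labels
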