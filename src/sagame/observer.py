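"""Synthetic observers: the data-generating model for the whole pipeline.

Each simulated participant is an equal-variance signal-detection observer.
For every probed location the observer draws a latent evidence value —
Normal(0, 1) for an empty location, Normal(d', 1) for a location with a
target — and selects the location when the evidence exceeds a decision
criterion λ (measured from the noise mean).  Sensitivity d', criterion,
and response-time means are phase-dependent (the 30 game clips split into
start / middle / end phases of 10 clips each), which implements a learning
trend.  Response times are lognormal.  A lapse parameter optionally replaces
a selection by a fair coin, to stress-test estimator robustness.

Gaze streams are generated at an effective sampling rate drawn uniformly in
[10, 30] Hz.  With probability ``p_look`` the trace enters an analysed AOI
for a Poisson number of glances (minimum one), the first after a lognormal
latency from target appearance, each with a lognormal dwell truncated at the
mask; otherwise (and between glances) the trace follows a center-biased
random walk kept outside the AOI.

The counting-span generator produces trials of set size 2..8, three trials
per size, recalling each tally correctly with a probability that collapses
once the set size exceeds the observer's working-memory capacity; the task
stops early after three consecutive trials whose recalled set is not exactly
correct.

Default profiles are seeded from the study's printed group means (hit/false
alarm structure per phase, gaze parameters and working-memory span for
children of 9-10 years versus adults), so that a simulated cohort reproduces
the qualitative group orderings of the original data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._rng import child_seed, rng_for
from .bank import ClipSpec, StimulusBank, randomize_order
from .gaze import AOITrack, GazeQuality

N_PHASES = 3


@dataclass(frozen=True)
class ObserverProfile:
    """Generative parameters of one synthetic observer."""

    group: str  # child | adult
    d_prime_by_phase: tuple[float, float, float]
    criterion_by_phase: tuple[float, float, float]  # λ on the noise axis (sd units)
    rt_mean_by_phase: tuple[float, float, float]  # seconds
    rt_sigma: float = 0.40  # lognormal shape
    p_look: float = 0.5  # probability of glancing at an analysed target
    glance_latency_mean: float = 2.0  # s from target appearance
    glance_latency_sigma: float = 0.40
    glance_dwell_mean: float = 1.0  # s per glance
    glance_dwell_sigma: float = 0.50
    glance_rate: float = 1.5  # expected glances per looked-at target
    wm_capacity: int = 5  # max set size reliably recalled
    wm_noise: float = 0.05  # per-tally error probability within capacity
    lapse_rate: float = 0.0

    def __post_init__(self):
        d = self.d_prime_by_phase
        if any(x < 0 for x in d) or any(d[i] > d[i + 1] + 1e-12 for i in range(2)):
            raise ValueError("d' must be non-negative and non-decreasing across phases")
        if not 0 <= self.p_look <= 1 or not 0 <= self.lapse_rate <= 1:
            raise ValueError("probabilities must lie in [0, 1]")
        if min(self.rt_mean_by_phase) <= 0 or self.glance_dwell_mean <= 0:
            raise ValueError("response-time and dwell parameters must be positive")


# Defaults seeded from the printed group means: per-phase d' and observed
# criterion, gaze statistics, and a working-memory span yielding child/adult
# PCU scores on either side of 0.5.
CHILD_PROFILE = ObserverProfile(
    group="child",
    d_prime_by_phase=(0.88, 1.06, 1.43),
    criterion_by_phase=(0.24, 0.28, 0.50),
    rt_mean_by_phase=(4.82, 4.15, 3.47),
    p_look=0.35, glance_latency_mean=2.48, glance_dwell_mean=0.74,
    glance_rate=2.01, wm_capacity=2, wm_noise=0.20,
)
ADULT_PROFILE = ObserverProfile(
    group="adult",
    d_prime_by_phase=(1.74, 1.82, 2.04),
    criterion_by_phase=(0.68, 0.76, 0.88),
    rt_mean_by_phase=(4.82, 4.15, 3.47),
    p_look=0.55, glance_latency_mean=1.97, glance_dwell_mean=1.16,
    glance_rate=1.49, wm_capacity=6,
)


@dataclass(frozen=True)
class ResponseRecord:
    participant_id: str
    clip_id: str
    location_id: str
    target_present: bool
    selected: bool


@dataclass(frozen=True)
class CountingSpanTrial:
    set_size: int
    true_tallies: tuple[int, ...]
    recalled_tallies: tuple[int, ...]

    @property
    def fully_correct(self) -> bool:
        return self.true_tallies == self.recalled_tallies


@dataclass(frozen=True)
class CountingSpanTranscript:
    trials: tuple[CountingSpanTrial, ...]
    stopped_early: bool


@dataclass
class ParticipantSession:
    participant_id: str
    profile: ObserverProfile
    order: list[str]
    responses: list[ResponseRecord]
    clip_rt: dict[str, float]  # seconds, mask onset -> answer check
    gaze: dict[str, pd.DataFrame] = field(default_factory=dict)
    quality: GazeQuality | None = None
    counting_span: CountingSpanTranscript | None = None


def _lognormal(rng: np.random.Generator, mean: float, sigma: float, size=None):
    """Lognormal draws parametrized by their arithmetic mean."""
    mu = math.log(mean) - sigma**2 / 2.0
    return rng.lognormal(mu, sigma, size)


def game_phase_of_position(pos: int) -> int:
    """Phase index (0, 1, 2) of a game clip at game-order position ``pos`` (0-based)."""
    return min(pos // 10, N_PHASES - 1)


def simulate_responses(profile: ObserverProfile, bank: StimulusBank,
                       order: Sequence[str], seed: int,
                       participant_id: str = "p0") -> ParticipantSession:
    """Simulate one participant's selections and response times.

    Practice clips are played with the start-phase parameters; game-clip
    phase is the clip's position in this participant's order (1-10, 11-20,
    21-30).  Deterministic for a fixed seed.
    """
    bank_ids = {c.clip_id for c in bank.clips}
    if set(order) != bank_ids or len(order) != len(bank_ids):
        raise ValueError("presentation order does not cover the bank exactly")

    rng = rng_for(seed, "responses")
    responses: list[ResponseRecord] = []
    clip_rt: dict[str, float] = {}
    game_pos = 0
    for clip_id in order:
        clip = bank.clip(clip_id)
        if clip.role == "game":
            phase = game_phase_of_position(game_pos)
            game_pos += 1
        else:
            phase = 0
        d = profile.d_prime_by_phase[phase]
        lam = profile.criterion_by_phase[phase]
        for loc in clip.locations:
            evidence = rng.normal(d if loc.has_target else 0.0, 1.0)
            selected = bool(evidence > lam)
            if profile.lapse_rate > 0 and rng.random() < profile.lapse_rate:
                selected = bool(rng.random() < 0.5)
            responses.append(ResponseRecord(participant_id, clip_id,
                                            loc.location_id, loc.has_target,
                                            selected))
        clip_rt[clip_id] = float(
            _lognormal(rng, profile.rt_mean_by_phase[phase], profile.rt_sigma))
    return ParticipantSession(participant_id=participant_id, profile=profile,
                              order=list(order), responses=responses,
                              clip_rt=clip_rt)


def _walk(rng: np.random.Generator, n: int, step_sd: float = 0.03) -> np.ndarray:
    """Center-biased (AR(1)) random walk on the unit square, shape (n, 2)."""
    from scipy.signal import lfilter

    # p_i = 0.95 p_{i-1} + 0.025 + e_i  -> stationary around screen center
    noise = rng.normal(0.025, step_sd, (n, 2))
    p0 = 0.5 + rng.normal(0, 0.05, 2)
    out = np.empty((n, 2))
    for k in range(2):
        out[:, k], _ = lfilter([1.0], [1.0, -0.95], noise[:, k],
                               zi=[0.95 * p0[k]])
    return np.clip(out, 0.0, 1.0)


def simulate_gaze(profile: ObserverProfile, clip: ClipSpec, aoi: AOITrack,
                  seed: int, calibration_error: float = 0.5,
                  p_invalid: float = 0.02):
    """Simulate one gaze stream for a clip with one analysed AOI.

    Returns ``(samples, effective_rate_hz)`` where ``samples`` has columns
    ``t_s, x, y, valid``.
    """
    if aoi.clip_id != clip.clip_id:
        raise ValueError("AOI track does not belong to this clip")
    rng = rng_for(seed, f"gaze:{clip.clip_id}")
    rate = float(rng.uniform(10.0, 30.0))
    t = np.arange(0.0, clip.mask_time, 1.0 / rate)
    n = len(t)
    xy = _walk(rng, n)

    window = aoi.end_time - aoi.appear_time
    glances: list[tuple[float, float]] = []
    if rng.random() < profile.p_look and window > 0.3:
        n_glances = max(1, int(rng.poisson(profile.glance_rate)))
        latency = float(_lognormal(rng, profile.glance_latency_mean,
                                   profile.glance_latency_sigma))
        latency = min(latency, max(window - 0.3, 0.05))
        onset = aoi.appear_time + latency
        for _ in range(n_glances):
            if onset >= aoi.end_time - 0.05:
                break
            dwell = float(_lognormal(rng, profile.glance_dwell_mean,
                                     profile.glance_dwell_sigma))
            offset = min(onset + dwell, aoi.end_time)
            glances.append((onset, offset))
            onset = offset + 0.2 + float(rng.exponential(0.5))

    cx, cy, r = aoi.circle_at(t)
    in_glance = np.zeros(n, dtype=bool)
    for on, off in glances:
        in_glance |= (t >= on) & (t <= off)

    # inside the AOI during glances: center plus jitter within half the radius
    jitter = rng.normal(0, 1, (n, 2))
    jitter /= np.maximum(np.linalg.norm(jitter, axis=1, keepdims=True), 1e-9)
    jitter *= (rng.uniform(0, 0.5, n)[:, None] * r[:, None])
    xy[in_glance, 0] = cx[in_glance] + jitter[in_glance, 0]
    xy[in_glance, 1] = cy[in_glance] + jitter[in_glance, 1]

    # outside glances: push strays out of the AOI so p_look is honoured
    dx, dy = xy[:, 0] - cx, xy[:, 1] - cy
    dist = np.hypot(dx, dy)
    stray = ~in_glance & (dist <= r) & (t >= aoi.appear_time) & (t <= aoi.end_time)
    if stray.any():
        scale = (r[stray] * 1.5 + 0.02) / np.maximum(dist[stray], 1e-9)
        xy[stray, 0] = cx[stray] + dx[stray] * scale
        xy[stray, 1] = cy[stray] + dy[stray] * scale

    valid = rng.random(n) >= p_invalid
    samples = pd.DataFrame({"t_s": t, "x": np.clip(xy[:, 0], -0.2, 1.2),
                            "y": np.clip(xy[:, 1], -0.2, 1.2), "valid": valid})
    return samples, rate


def simulate_counting_span(wm_capacity: int, noise: float, seed: int,
                           overload_penalty: float = 0.25,
                           max_set_size: int = 8,
                           trials_per_size: int = 3) -> CountingSpanTranscript:
    """Simulate a counting-span run: set sizes 2..8, three trials each.

    A tally is recalled correctly with probability ``1 - noise`` when the
    trial's set size is within capacity, decaying by ``overload_penalty`` per
    item beyond capacity.  The task stops early after three consecutive
    trials whose recalled set is not exactly correct.
    """
    if wm_capacity < 0:
        raise ValueError("wm_capacity must be >= 0")
    rng = rng_for(seed, "span")
    trials: list[CountingSpanTrial] = []
    consecutive_failures = 0
    stopped = False
    for set_size in range(2, max_set_size + 1):
        for _ in range(trials_per_size):
            true = rng.integers(2, 9, size=set_size)
            p_correct = (1.0 - noise if set_size <= wm_capacity
                         else max(0.0, 1.0 - noise
                                  - overload_penalty * (set_size - wm_capacity)))
            correct = rng.random(set_size) < p_correct
            recalled = true.copy()
            for i in np.flatnonzero(~correct):
                wrong = rng.integers(2, 9)
                while wrong == true[i]:
                    wrong = rng.integers(2, 9)
                recalled[i] = wrong
            trial = CountingSpanTrial(set_size, tuple(int(v) for v in true),
                                      tuple(int(v) for v in recalled))
            trials.append(trial)
            consecutive_failures = 0 if trial.fully_correct else consecutive_failures + 1
            if consecutive_failures >= 3:
                stopped = True
                break
        if stopped:
            break
    return CountingSpanTranscript(tuple(trials), stopped_early=stopped)


def jitter_profile(profile: ObserverProfile, rng: np.random.Generator,
                   d_prime_sd: float = 0.5, criterion_sd: float = 0.3) -> ObserverProfile:
    """Between-subject heterogeneity: a common Gaussian shift of d' and λ.

    The shift is shared across phases so the learning trend is preserved;
    d' is floored at 0.05 to keep sensitivities non-negative.
    """
    dd = rng.normal(0, d_prime_sd)
    dl = rng.normal(0, criterion_sd)
    return replace(
        profile,
        d_prime_by_phase=tuple(max(0.05, v + dd) for v in profile.d_prime_by_phase),
        criterion_by_phase=tuple(v + dl for v in profile.criterion_by_phase),
    )


def simulate_cohort(n_children: int, n_adults: int, bank: StimulusBank,
                    seed: int, child_profile: ObserverProfile = CHILD_PROFILE,
                    adult_profile: ObserverProfile = ADULT_PROFILE,
                    aoi_tracks: Mapping[str, AOITrack] | None = None,
                    d_prime_sd: float = 0.5, criterion_sd: float = 0.3,
                    include_gaze: bool = True,
                    include_counting_span: bool = True) -> list[ParticipantSession]:
    """Simulate a full cohort, one independent order and seed per participant."""
    if n_children < 0 or n_adults < 0:
        raise ValueError("cohort sizes must be >= 0")
    sessions: list[ParticipantSession] = []
    specs = ([("child", child_profile)] * n_children
             + [("adult", adult_profile)] * n_adults)
    track_by_clip: dict[str, AOITrack] = {}
    if include_gaze and aoi_tracks:
        track_by_clip = {tr.clip_id: tr for tr in aoi_tracks.values()}
    for i, (group, base) in enumerate(specs):
        pid = f"{group[0]}{i + 1:03d}"
        pseed = child_seed(seed, f"participant:{pid}")
        rng = rng_for(pseed, "profile")
        profile = jitter_profile(base, rng, d_prime_sd, criterion_sd)
        order = randomize_order(bank, pseed)
        session = simulate_responses(profile, bank, order, pseed, pid)
        if include_counting_span:
            session.counting_span = simulate_counting_span(
                profile.wm_capacity, profile.wm_noise, pseed)
        if track_by_clip:
            rates = {}
            for clip_id, track in track_by_clip.items():
                samples, rate = simulate_gaze(profile, bank.clip(clip_id),
                                              track, pseed)
                session.gaze[clip_id] = samples
                rates[clip_id] = rate
            session.quality = GazeQuality(participant_id=pid,
                                          calibration_error=float(
                                              rng.uniform(0.3, 1.5)),
                                          clip_rates=rates)
        sessions.append(session)
    return sessions


# ---------------------------------------------------------------------------
# tabular serialization

def responses_to_frame(sessions: Sequence[ParticipantSession]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"participant_id": r.participant_id, "clip_id": r.clip_id,
          "location_id": r.location_id, "target_present": r.target_present,
          "selected": r.selected}
         for s in sessions for r in s.responses]
    )


def rts_to_frame(sessions: Sequence[ParticipantSession]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"participant_id": s.participant_id, "clip_id": c, "rt_s": rt,
          "position": s.order.index(c)}
         for s in sessions for c, rt in s.clip_rt.items()]
    )
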