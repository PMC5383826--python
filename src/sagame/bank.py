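"""Synthetic stimulus banks for the situation-awareness video game.

A bank mimics the structure of the game's stimulus set: 30 game clips plus 3
practice clips, each stopped and masked at a predefined moment, with two or
three probed screen locations per clip.  Each location either holds an overt
target (a visible road user), a covert target (an occlusion behind which a
road user could emerge) or nothing.  The canonical game composition is 33
overt, 12 covert and 34 empty locations over the 30 game clips, giving a
target prevalence of 45/79.

Two structural constraints from the original stimulus set are enforced:

* a three-location clip never contains more than two targets (every clip has
  at least one empty location), and
* among two-location clips, clips with exactly one target outnumber clips
  with two targets.

Coordinates are normalized to the unit square (origin top-left) so the bank
is independent of any physical display size.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import rng_for

KINDS = ("overt", "covert", "empty")


@dataclass(frozen=True)
class LocationSpec:
    """One probed location within a clip."""

    clip_id: str
    location_id: str
    kind: str  # overt | covert | empty
    x: float  # normalized, origin top-left
    y: float
    radius: float

    @property
    def has_target(self) -> bool:
        return self.kind != "empty"


@dataclass(frozen=True)
class ClipSpec:
    """One video clip: role, timing and its probed locations."""

    clip_id: str
    role: str  # game | practice
    duration: float  # seconds
    mask_time: float  # seconds; moment the video is masked
    locations: tuple[LocationSpec, ...]

    @property
    def n_targets(self) -> int:
        return sum(loc.has_target for loc in self.locations)


@dataclass(frozen=True)
class BankConfig:
    """Composition and duration parameters of a stimulus bank."""

    n_game_clips: int = 30
    n_practice_clips: int = 3
    n_overt: int = 33
    n_covert: int = 12
    n_empty: int = 34
    duration_mean: float = 11.47
    duration_sd: float = 5.08
    duration_min: float = 4.81
    duration_max: float = 24.19
    radius: float = 0.08


@dataclass(frozen=True)
class StimulusBank:
    clips: tuple[ClipSpec, ...]
    config: BankConfig = field(default_factory=BankConfig)
    seed: int | None = None

    @property
    def game_clips(self) -> tuple[ClipSpec, ...]:
        return tuple(c for c in self.clips if c.role == "game")

    @property
    def practice_clips(self) -> tuple[ClipSpec, ...]:
        return tuple(c for c in self.clips if c.role == "practice")

    @property
    def prevalence(self) -> float:
        """Fraction of game locations holding a target (the SDT prior s)."""
        locs = [l for c in self.game_clips for l in c.locations]
        return sum(l.has_target for l in locs) / len(locs)

    def clip(self, clip_id: str) -> ClipSpec:
        for c in self.clips:
            if c.clip_id == clip_id:
                return c
        raise KeyError(clip_id)


class BankConfigError(ValueError):
    """Raised when a bank configuration cannot be realized."""


def _solve_composition(cfg: BankConfig, rng: np.random.Generator):
    """Assign per-clip location and target counts satisfying the totals.

    Returns a list of (n_locations, n_targets) per game clip.
    """
    n = cfg.n_game_clips
    total = cfg.n_overt + cfg.n_covert + cfg.n_empty
    targets = cfg.n_overt + cfg.n_covert

    n3 = total - 2 * n  # clips with three locations
    if not 0 <= n3 <= n:
        raise BankConfigError(
            f"{total} locations cannot be split into {n} clips of 2-3 "
            "locations (location-count rule)"
        )
    n2 = n - n3
    two_target_total = targets - n  # each clip holds 1 or 2 targets
    if not 0 <= two_target_total <= n:
        raise BankConfigError(
            f"{targets} targets cannot be split into {n} clips of 1-2 "
            "targets (target-count rule)"
        )

    # b = two-location clips holding two targets; remaining two-target clips
    # are three-location clips (which then keep one empty location, so the
    # at-most-two-targets rule holds automatically).
    b_lo = max(0, two_target_total - n3)
    b_hi = min(n2, two_target_total)
    if n2 > 0:
        b_hi = min(b_hi, (n2 - 1) // 2)  # one-target majority among 2-loc clips
    if b_lo > b_hi:
        raise BankConfigError(
            "composition incompatible with the one-target-majority rule for "
            "two-location clips"
        )
    b = int(rng.integers(b_lo, b_hi + 1))

    counts = (
        [(2, 2)] * b
        + [(2, 1)] * (n2 - b)
        + [(3, 2)] * (two_target_total - b)
        + [(3, 1)] * (n3 - (two_target_total - b))
    )
    rng.shuffle(counts)
    return counts


def _sample_durations(cfg: BankConfig, n: int, rng: np.random.Generator,
                      match_mean: bool) -> np.ndarray:
    a = (cfg.duration_min - cfg.duration_mean) / cfg.duration_sd
    b = (cfg.duration_max - cfg.duration_mean) / cfg.duration_sd
    d = stats.truncnorm.rvs(a, b, loc=cfg.duration_mean, scale=cfg.duration_sd,
                            size=n, random_state=rng)
    if match_mean and n > 0:
        # shift-and-clip until the sample mean equals the target mean exactly
        for _ in range(200):
            d = np.clip(d + (cfg.duration_mean - d.mean()),
                        cfg.duration_min, cfg.duration_max)
            if abs(d.mean() - cfg.duration_mean) < 1e-12:
                break
        else:  # pragma: no cover - clip bound pathologies
            raise BankConfigError("cannot match the requested mean duration")
    return d


def _sample_centers(k: int, radius: float, rng: np.random.Generator):
    """k circle centers in the unit square, pairwise non-overlapping."""
    lo, hi = 0.12, 0.88
    for _ in range(1000):
        pts = rng.uniform(lo, hi, size=(k, 2))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        if np.all(d[np.triu_indices(k, 1)] > 2.5 * radius):
            return pts
    raise BankConfigError("cannot place non-overlapping locations")  # pragma: no cover


def _build_clip(clip_id: str, role: str, duration: float, kinds: Sequence[str],
                radius: float, rng: np.random.Generator) -> ClipSpec:
    centers = _sample_centers(len(kinds), radius, rng)
    locs = tuple(
        LocationSpec(clip_id=clip_id, location_id=f"{clip_id}_L{i + 1}",
                     kind=k, x=float(c[0]), y=float(c[1]), radius=radius)
        for i, (k, c) in enumerate(zip(kinds, centers))
    )
    return ClipSpec(clip_id=clip_id, role=role, duration=float(duration),
                    mask_time=float(duration), locations=locs)


# practice clips have a fixed composition: every location kind appears
_PRACTICE_KINDS = (("overt", "empty"), ("covert", "empty"),
                   ("overt", "covert", "empty"))


def generate_bank(config: BankConfig | None = None, seed: int = 0) -> StimulusBank:
    """Generate a stimulus bank satisfying every structural invariant.

    Deterministic for a fixed ``(config, seed)``.  Raises
    :class:`BankConfigError` when the configuration is infeasible.
    """
    cfg = config or BankConfig()
    rng = rng_for(seed, "bank")

    counts = _solve_composition(cfg, rng)
    # distribute overt/covert labels over the target slots
    target_labels = ["overt"] * cfg.n_overt + ["covert"] * cfg.n_covert
    rng.shuffle(target_labels)
    it = iter(target_labels)

    durations = _sample_durations(cfg, cfg.n_game_clips, rng, match_mean=True)
    clips = []
    for i, (n_loc, n_tgt) in enumerate(counts):
        kinds = [next(it) for _ in range(n_tgt)] + ["empty"] * (n_loc - n_tgt)
        rng.shuffle(kinds)
        clips.append(_build_clip(f"G{i + 1:02d}", "game", durations[i], kinds,
                                 cfg.radius, rng))

    practice_durations = _sample_durations(cfg, cfg.n_practice_clips, rng,
                                           match_mean=False)
    for j in range(cfg.n_practice_clips):
        kinds = list(_PRACTICE_KINDS[j % len(_PRACTICE_KINDS)])
        clips.append(_build_clip(f"P{j + 1}", "practice",
                                 practice_durations[j], kinds, cfg.radius, rng))

    return StimulusBank(clips=tuple(clips), config=cfg, seed=seed)


def validate_bank(bank: StimulusBank) -> list[str]:
    """Check every structural invariant; returns a list of violations.

    An empty list means the bank is valid.  Validation never raises.
    """
    v: list[str] = []
    cfg = bank.config
    game = bank.game_clips
    if len(game) != cfg.n_game_clips:
        v.append(f"bank: expected {cfg.n_game_clips} game clips, found {len(game)}")
    if len(bank.practice_clips) != cfg.n_practice_clips:
        v.append(f"bank: expected {cfg.n_practice_clips} practice clips, "
                 f"found {len(bank.practice_clips)}")

    for c in bank.clips:
        if not 2 <= len(c.locations) <= 3:
            v.append(f"{c.clip_id}: location-count rule (2-3 per clip), "
                     f"found {len(c.locations)}")
        if len(c.locations) == 3 and c.n_targets > 2:
            v.append(f"{c.clip_id}: more than two targets in a three-location clip")
        if not 0 < c.mask_time <= c.duration:
            v.append(f"{c.clip_id}: mask_time outside (0, duration]")
        for loc in c.locations:
            if loc.kind not in KINDS:
                v.append(f"{c.clip_id}/{loc.location_id}: unknown kind {loc.kind!r}")
            if not (0 <= loc.x <= 1 and 0 <= loc.y <= 1):
                v.append(f"{c.clip_id}/{loc.location_id}: center outside unit square")
            if loc.radius <= 0:
                v.append(f"{c.clip_id}/{loc.location_id}: non-positive radius")

    kinds = [l.kind for c in game for l in c.locations]
    comp = {k: kinds.count(k) for k in KINDS}
    want = {"overt": cfg.n_overt, "covert": cfg.n_covert, "empty": cfg.n_empty}
    if comp != want:
        v.append(f"bank: game composition {comp} differs from {want}")

    two_loc = [c for c in game if len(c.locations) == 2]
    one_t = sum(c.n_targets == 1 for c in two_loc)
    two_t = sum(c.n_targets == 2 for c in two_loc)
    if two_loc and not one_t > two_t:
        v.append("bank: two-location clips with one target do not outnumber "
                 "those with two targets")

    for c in game:
        if not cfg.duration_min <= c.duration <= cfg.duration_max:
            v.append(f"{c.clip_id}: duration outside "
                     f"[{cfg.duration_min}, {cfg.duration_max}]")
    return v


def randomize_order(bank: StimulusBank, seed: int) -> list[str]:
    """Presentation order: practice clips first (fixed), game clips permuted."""
    rng = rng_for(seed, "order")
    game_ids = [c.clip_id for c in bank.game_clips]
    perm = list(rng.permutation(game_ids))
    return [c.clip_id for c in bank.practice_clips] + [str(g) for g in perm]


# ---------------------------------------------------------------------------
# serialization: one row per location + a JSON sidecar with config and seed

def bank_to_frame(bank: StimulusBank) -> pd.DataFrame:
    rows = [
        {"clip_id": c.clip_id, "role": c.role, "duration_s": c.duration,
         "mask_time_s": c.mask_time, "location_id": l.location_id,
         "kind": l.kind, "x": l.x, "y": l.y, "radius": l.radius}
        for c in bank.clips for l in c.locations
    ]
    return pd.DataFrame(rows)


def bank_from_frame(df: pd.DataFrame, config: BankConfig | None = None,
                    seed: int | None = None) -> StimulusBank:
    clips = []
    for clip_id, g in df.groupby("clip_id", sort=False):
        first = g.iloc[0]
        locs = tuple(
            LocationSpec(clip_id=str(clip_id), location_id=str(r.location_id),
                         kind=str(r.kind), x=float(r.x), y=float(r.y),
                         radius=float(r.radius))
            for r in g.itertuples()
        )
        clips.append(ClipSpec(clip_id=str(clip_id), role=str(first.role),
                              duration=float(first.duration_s),
                              mask_time=float(first.mask_time_s),
                              locations=locs))
    return StimulusBank(clips=tuple(clips), config=config or BankConfig(),
                        seed=seed)


def write_bank(bank: StimulusBank, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    # %.17g round-trips IEEE doubles exactly
    bank_to_frame(bank).to_csv(out / "bank.csv", index=False,
                               float_format="%.17g")
    sidecar = {"config": asdict(bank.config), "seed": bank.seed,
               "schema_version": 1}
    (out / "bank.json").write_text(json.dumps(sidecar, indent=2))
    return out / "bank.csv"


def read_bank(path: str | Path) -> StimulusBank:
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    cfg, seed = BankConfig(), None
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        cfg = BankConfig(**meta["config"])
        seed = meta.get("seed")
    return bank_from_frame(df, config=cfg, seed=seed)
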