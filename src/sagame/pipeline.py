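"""End-to-end study pipeline: bank → cohort → scoring → metrics → inference.

``run_study`` executes every stage on a single root seed and returns a
:class:`StudyReport` whose tables mirror the reporting style of the original
study: per-location-type percent correct by group (game versus practice),
SDT measures by phase and group, gaze parameters by group, and an inference
block with the group comparisons, learning ANOVAs and the working-memory /
gaze regressions.  Identical config + seed produce byte-identical reports.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from ._rng import child_seed
from .bank import BankConfig, StimulusBank, generate_bank, validate_bank, write_bank
from .game import game_points
from .gaze import (GazeParams, apply_exclusions, detect_glances,
                   make_aoi_tracks, participant_gaze_summary, summaries_to_frame,
                   tracks_to_frame)
from .observer import (ADULT_PROFILE, CHILD_PROFILE, ObserverProfile,
                       ParticipantSession, responses_to_frame, rts_to_frame,
                       simulate_cohort)
from .sdt import cohort_metrics_frame
from .stats import (linear_contrast, mixed_anova, nested_f, ols_regression,
                    pearson_r, welch_t)

log = logging.getLogger("sagame")


@dataclass(frozen=True)
class StudyConfig:
    seed: int = 0
    n_children: int = 36
    n_adults: int = 22
    bank: BankConfig = field(default_factory=BankConfig)
    child_profile: ObserverProfile = CHILD_PROFILE
    adult_profile: ObserverProfile = ADULT_PROFILE
    gaze_params: GazeParams = field(default_factory=GazeParams)
    d_prime_sd: float = 0.5
    criterion_sd: float = 0.3
    n_aoi_targets: int = 10
    include_gaze: bool = True

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "StudyConfig":
        raw = json.loads(text)
        raw["bank"] = BankConfig(**raw.get("bank", {}))
        for key in ("child_profile", "adult_profile"):
            if key in raw:
                prof = raw[key]
                for f in ("d_prime_by_phase", "criterion_by_phase",
                          "rt_mean_by_phase"):
                    prof[f] = tuple(prof[f])
                raw[key] = ObserverProfile(**prof)
        if "gaze_params" in raw:
            raw["gaze_params"] = GazeParams(**raw["gaze_params"])
        return cls(**raw)


@dataclass
class StudyReport:
    config_hash: str
    seed: int
    version: str
    table1: pd.DataFrame  # percent correct by location type x group
    table2: pd.DataFrame  # SDT measures by phase x group
    table3: pd.DataFrame | None  # gaze parameters by group
    inference: dict[str, Any]
    attrition: dict[str, Any]

    def to_dict(self) -> dict[str, Any]:
        return {
            "provenance": {"config_hash": self.config_hash, "seed": self.seed,
                           "version": self.version, "schema_version": 1},
            "table1": self.table1.to_dict(orient="records"),
            "table2": self.table2.to_dict(orient="records"),
            "table3": (self.table3.to_dict(orient="records")
                       if self.table3 is not None else None),
            "inference": self.inference,
            "attrition": self.attrition,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=2,
                          default=_jsonify)


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return dataclasses.asdict(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")  # pragma: no cover


def _round6(x):
    return None if x is None else float(np.round(x, 6))


def _location_type_table(sessions, bank: StimulusBank) -> pd.DataFrame:
    """Per-group mean percent correct by location kind, game vs practice."""
    kind = {l.location_id: l.kind for c in bank.clips for l in c.locations}
    role = {c.clip_id: c.role for c in bank.clips}
    rows = []
    for s in sessions:
        df = pd.DataFrame([{"kind": kind[r.location_id],
                            "role": role[r.clip_id],
                            "correct": r.selected == r.target_present}
                           for r in s.responses])
        for (rl, k), g in df.groupby(["role", "kind"]):
            rows.append({"participant_id": s.participant_id,
                         "group": s.profile.group, "role": rl, "kind": k,
                         "pct_correct": 100.0 * g["correct"].mean()})
    per = pd.DataFrame(rows)
    out = (per.groupby(["role", "kind", "group"])["pct_correct"]
           .agg(mean="mean", sd="std").reset_index())
    return out.round(6)


def _anova_block(metrics: pd.DataFrame, dv: str, two_groups: bool) -> dict:
    phases = metrics[metrics["window"] != "overall"]
    # complete cases only: drop participants with an undefined value in any
    # window (e.g. bias is undefined where the estimated d' is exactly 0)
    bad = phases.loc[phases[dv].isna(), "participant_id"].unique()
    if len(bad):
        phases = phases[~phases["participant_id"].isin(bad)]
    if two_groups:
        res = mixed_anova(phases, dv=dv, within="window",
                          subject="participant_id", between="group")
    else:
        res = mixed_anova(phases.assign(group="all"), dv=dv, within="window",
                          subject="participant_id", between="group")
    wide = phases.pivot_table(index="participant_id", columns="window",
                              values=dv)[["start", "middle", "end"]]
    contrast = linear_contrast(wide.to_numpy())
    return {"anova": res, "linear_contrast": contrast}


def run_study(config: StudyConfig, out_dir: str | Path | None = None) -> StudyReport:
    """Run the full pipeline for one study configuration."""
    cfg = config
    config_hash = hashlib.sha256(cfg.to_json().encode()).hexdigest()[:16]

    bank = generate_bank(cfg.bank, seed=child_seed(cfg.seed, "stage:bank"))
    violations = validate_bank(bank)
    if violations:  # pragma: no cover - generator postcondition
        raise RuntimeError(f"bank stage: invalid bank: {violations[0]}")
    log.info("bank: %d clips, prevalence %.4f", len(bank.clips), bank.prevalence)

    tracks = (make_aoi_tracks(bank, cfg.n_aoi_targets,
                              seed=child_seed(cfg.seed, "stage:aoi"))
              if cfg.include_gaze else None)
    sessions = simulate_cohort(
        cfg.n_children, cfg.n_adults, bank,
        seed=child_seed(cfg.seed, "stage:cohort"),
        child_profile=cfg.child_profile, adult_profile=cfg.adult_profile,
        aoi_tracks=tracks, d_prime_sd=cfg.d_prime_sd,
        criterion_sd=cfg.criterion_sd, include_gaze=cfg.include_gaze)
    log.info("cohort: %d sessions", len(sessions))

    metrics = cohort_metrics_frame(sessions, bank)
    points = pd.Series({s.participant_id: game_points(s, bank) for s in sessions})
    groups = {s.participant_id: s.profile.group for s in sessions}

    table1 = _location_type_table(sessions, bank)
    overall = metrics[metrics["window"] == "overall"].set_index("participant_id")
    by_phase = metrics[metrics["window"] != "overall"]
    table2 = (by_phase.groupby(["window", "group"])
              [["raw_hit_rate", "raw_fa_rate", "d_prime", "lambda_obs",
                "lambda_opt", "bias", "accuracy", "rt_s"]]
              .agg(["mean", "std"]))
    table2.columns = ["_".join(c) for c in table2.columns]
    table2 = table2.reset_index().round(6)

    # gaze stage with quality exclusions
    table3 = None
    gaze_summaries = None
    attrition: dict[str, Any] = {"n_sessions": len(sessions)}
    if cfg.include_gaze and tracks:
        streams = {s.participant_id: s.gaze for s in sessions}
        qualities = [s.quality for s in sessions if s.quality is not None]
        retained, exc_log = apply_exclusions(qualities, streams, cfg.gaze_params)
        summaries = []
        for pid, clips in retained.items():
            events = {}
            for tid, tr in tracks.items():
                if tr.clip_id in clips:
                    events[tid] = detect_glances(clips[tr.clip_id], tr,
                                                 cfg.gaze_params)
            if events:
                summaries.append(participant_gaze_summary(events, tracks, pid))
        gaze_summaries = summaries_to_frame(summaries)
        gaze_summaries["group"] = gaze_summaries["participant_id"].map(groups)
        table3 = (gaze_summaries.groupby("group")
                  [["pct_targets_looked", "avg_glance_freq",
                    "avg_first_glance_latency", "avg_dwell_time"]]
                  .agg(["mean", "std"]))
        table3.columns = ["_".join(c) for c in table3.columns]
        table3 = table3.reset_index().round(6)
        attrition["gaze_excluded"] = [list(e) for e in exc_log]
        attrition["gaze_retained"] = len(summaries)
        log.info("gaze: retained %d participants, %d exclusions",
                 len(summaries), len(exc_log))

    # inference block
    inference: dict[str, Any] = {}
    have_two_groups = cfg.n_children > 0 and cfg.n_adults > 0
    child_ids = [p for p, g in groups.items() if g == "child"]
    adult_ids = [p for p, g in groups.items() if g == "adult"]

    inference["accuracy_points_r"] = pearson_r(
        overall["accuracy"].to_numpy(), points[overall.index].to_numpy())

    if have_two_groups:
        acc = overall["accuracy"]
        inference["accuracy_welch"] = welch_t(acc[adult_ids], acc[child_ids])
        inference["points_welch"] = welch_t(points[adult_ids], points[child_ids])
        pcu = overall["pcu"].dropna()
        if len(pcu) == len(overall):
            inference["pcu_welch"] = welch_t(pcu[adult_ids], pcu[child_ids])

    for dv in ("accuracy", "d_prime", "rt_s", "bias"):
        inference[f"{dv}_by_phase"] = _anova_block(metrics, dv, have_two_groups)

    # working-memory regressions on logit accuracy
    if overall["pcu"].notna().all() and len(overall) > 3:
        y = overall["logit_accuracy"].to_numpy()
        x_pcu = overall["pcu"].to_numpy()[:, None]
        x_grp = np.asarray(overall.index.map(groups) == "adult",
                           dtype=float)[:, None]
        m1 = ols_regression(y, x_pcu, names=["pcu"])
        inference["wm_model1_pcu"] = m1
        if have_two_groups:
            m2 = ols_regression(y, x_grp, names=["age_group"])
            m3 = ols_regression(y, np.hstack([x_pcu, x_grp]),
                                names=["pcu", "age_group"])
            inference["wm_model2_group"] = m2
            inference["wm_model3_both"] = m3
            inference["wm_add_group_to_pcu"] = nested_f(m1, m3)
            inference["wm_add_pcu_to_group"] = nested_f(m2, m3)

    if gaze_summaries is not None and len(gaze_summaries) > 3:
        from .gaze import gaze_accuracy_regression

        gs = gaze_summaries.set_index("participant_id")
        logit_acc = overall["logit_accuracy"].reindex(gs.index)
        inference["gaze_regressions"] = gaze_accuracy_regression(gs, logit_acc)

    report = StudyReport(config_hash=config_hash, seed=cfg.seed,
                         version=__version__, table1=table1, table2=table2,
                         table3=table3, inference=inference,
                         attrition=attrition)

    if out_dir is not None:
        write_report(report, out_dir, bank=bank, sessions=sessions,
                     metrics=metrics, tracks=tracks,
                     gaze_summaries=gaze_summaries, config=cfg)
    return report


def write_report(report: StudyReport, out_dir: str | Path,
                 bank: StimulusBank | None = None, sessions=None,
                 metrics: pd.DataFrame | None = None, tracks=None,
                 gaze_summaries: pd.DataFrame | None = None,
                 config: StudyConfig | None = None) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(report.to_json())
    report.table1.to_csv(out / "table1_location_types.csv", index=False)
    report.table2.to_csv(out / "table2_sdt_by_phase.csv", index=False)
    if report.table3 is not None:
        report.table3.to_csv(out / "table3_gaze.csv", index=False)
    if config is not None:
        (out / "config.json").write_text(config.to_json())
    if bank is not None:
        write_bank(bank, out)
    if sessions:
        responses_to_frame(sessions).to_csv(out / "responses.csv", index=False)
        rts_to_frame(sessions).to_csv(out / "response_times.csv", index=False)
    if metrics is not None:
        metrics.to_csv(out / "metrics.csv", index=False)
    if tracks:
        tracks_to_frame(tracks).to_csv(out / "aoi_tracks.csv", index=False)
    if gaze_summaries is not None:
        gaze_summaries.to_csv(out / "gaze_summaries.csv", index=False)
    return out / "report.json"


def read_report(path: str | Path) -> dict[str, Any]:
    """Read a serialized report, enforcing the schema version."""
    raw = json.loads(Path(path).read_text())
    version = raw.get("provenance", {}).get("schema_version")
    if version != 1:
        raise ValueError(f"unsupported report schema version: {version!r}")
    return raw
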