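"""Equal-variance signal-detection measures and working-memory scoring.

Per participant and aggregation window the module computes:

* accuracy — proportion of locations answered correctly (uncorrected);
* log-linear corrected hit and false-alarm rates: 0.5 is added to the hit
  and false-alarm counts and 1 to the signal and noise trial counts, so
  rates of exactly 0 or 1 cannot occur;
* sensitivity d' = Φ⁻¹(hit rate) − Φ⁻¹(false-alarm rate);
* the observed decision criterion λ_obs = −Φ⁻¹(false-alarm rate), measured
  on the evidence axis from the noise mean (a conservative responder who
  rarely selects has a high positive criterion);
* the accuracy-optimal criterion λ_opt = d'/2 − logit(s)/d' given the target
  prevalence s (when targets are more common than empties, logit(s) > 0 and
  the optimal criterion shifts liberally below the midpoint);
* response bias = λ_obs − λ_opt (negative: biased toward selecting);
* the partial-credit unit (PCU) score of a counting-span transcript: the
  mean over administered trials of the per-trial proportion of tallies
  recalled in the correct position.

Overt and covert targets are collapsed into "signal" throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .bank import StimulusBank
from .game import partition_phases
from .observer import CountingSpanTranscript, ParticipantSession, ResponseRecord

WINDOWS = ("start", "middle", "end", "overall")


@dataclass(frozen=True)
class ConfusionCounts:
    hits: int
    misses: int
    false_alarms: int
    correct_rejections: int

    def __post_init__(self):
        if min(self.hits, self.misses, self.false_alarms,
               self.correct_rejections) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n_signal(self) -> int:
        return self.hits + self.misses

    @property
    def n_noise(self) -> int:
        return self.false_alarms + self.correct_rejections

    @property
    def n_total(self) -> int:
        return self.n_signal + self.n_noise


@dataclass(frozen=True)
class SDTSummary:
    hit_rate: float  # log-linear corrected
    fa_rate: float  # log-linear corrected
    accuracy: float  # uncorrected proportion correct
    d_prime: float
    lambda_obs: float
    lambda_opt: float
    bias: float  # lambda_obs - lambda_opt
    prevalence_s: float
    counts: ConfusionCounts


@dataclass(frozen=True)
class CountingSpanScore:
    pcu: float
    tallies_presented: int
    tallies_correct: int


def tally_counts(responses: Iterable[ResponseRecord],
                 clip_ids: Iterable[str] | None = None) -> ConfusionCounts:
    """Confusion counts over a window of responses (optionally by clip)."""
    window = None if clip_ids is None else set(clip_ids)
    h = m = fa = cr = 0
    for r in responses:
        if window is not None and r.clip_id not in window:
            continue
        if r.target_present:
            h += r.selected
            m += not r.selected
        else:
            fa += r.selected
            cr += not r.selected
    counts = ConfusionCounts(h, m, fa, cr)
    if counts.n_total == 0:
        raise ValueError("empty response window")
    return counts


def loglinear_rates(counts: ConfusionCounts) -> tuple[float, float]:
    """Log-linear corrected (hit_rate, fa_rate), always strictly in (0, 1)."""
    if counts.n_signal < 1 or counts.n_noise < 1:
        raise ValueError("need at least one signal and one noise trial")
    hit = (counts.hits + 0.5) / (counts.n_signal + 1)
    fa = (counts.false_alarms + 0.5) / (counts.n_noise + 1)
    return hit, fa


def _check_rate(p: float, name: str) -> None:
    if not 0.0 < p < 1.0:
        raise ValueError(
            f"{name} must lie strictly in (0, 1); apply the log-linear "
            "correction to boundary rates")


def dprime(hit_rate: float, fa_rate: float) -> float:
    """Sensitivity d' = Φ⁻¹(hit rate) − Φ⁻¹(false-alarm rate)."""
    _check_rate(hit_rate, "hit_rate")
    _check_rate(fa_rate, "fa_rate")
    return float(norm.ppf(hit_rate) - norm.ppf(fa_rate))


def observed_criterion(fa_rate: float) -> float:
    """λ_obs = −Φ⁻¹(false-alarm rate), on the noise axis.

    Positive values mean a conservative criterion (fewer selections than a
    coin flip on empty locations).
    """
    _check_rate(fa_rate, "fa_rate")
    return float(-norm.ppf(fa_rate))


def logit(p: float) -> float:
    _check_rate(p, "proportion")
    return math.log(p / (1.0 - p))


def optimal_criterion(d_prime: float, prevalence_s: float) -> float:
    """Accuracy-maximizing criterion λ_opt = d'/2 − logit(s)/d'."""
    if d_prime == 0:
        raise ValueError("optimal criterion is undefined at zero sensitivity")
    _check_rate(prevalence_s, "prevalence_s")
    return 0.5 * d_prime - logit(prevalence_s) / d_prime


def response_bias(lambda_obs: float, lambda_opt: float) -> float:
    """Bias = observed − optimal criterion; negative favours selecting."""
    return lambda_obs - lambda_opt


def accuracy(counts: ConfusionCounts) -> float:
    """Proportion of locations correctly selected or unselected."""
    if counts.n_total < 1:
        raise ValueError("need at least one location")
    return (counts.hits + counts.correct_rejections) / counts.n_total


def logit_accuracy(acc: float) -> float:
    """ln(accuracy / (1 − accuracy)); raises at the boundaries."""
    return logit(acc)


def safe_logit_accuracy(counts: ConfusionCounts) -> float:
    """Logit accuracy, shrinking boundary values by (k + 0.5)/(n + 1).

    Interior accuracies are transformed untouched; exact 0 or 1 accuracies
    get the same flavour of shrinkage as the log-linear rate correction.
    """
    acc = accuracy(counts)
    if acc in (0.0, 1.0):
        k = counts.hits + counts.correct_rejections
        acc = (k + 0.5) / (counts.n_total + 1)
    return logit(acc)


def summarize_counts(counts: ConfusionCounts, prevalence_s: float) -> SDTSummary:
    hit, fa = loglinear_rates(counts)
    d = dprime(hit, fa)
    lam_obs = observed_criterion(fa)
    # an estimated d' of exactly 0 leaves the optimal criterion (and hence
    # bias) undefined for that window; propagate NaN rather than failing
    lam_opt = (optimal_criterion(d, prevalence_s) if d != 0.0 else math.nan)
    return SDTSummary(hit_rate=hit, fa_rate=fa, accuracy=accuracy(counts),
                      d_prime=d, lambda_obs=lam_obs, lambda_opt=lam_opt,
                      bias=response_bias(lam_obs, lam_opt),
                      prevalence_s=prevalence_s, counts=counts)


def pcu_score(transcript: CountingSpanTranscript) -> CountingSpanScore:
    """Partial-credit unit score of a counting-span transcript.

    The mean, over administered trials, of each trial's proportion of
    positionally correct tallies; trials never reached because of an early
    stop do not enter the average.
    """
    if not transcript.trials:
        raise ValueError("empty counting-span transcript")
    props = []
    presented = correct = 0
    for tr in transcript.trials:
        ok = sum(a == b for a, b in zip(tr.true_tallies, tr.recalled_tallies))
        props.append(ok / tr.set_size)
        presented += tr.set_size
        correct += ok
    return CountingSpanScore(pcu=float(np.mean(props)),
                             tallies_presented=presented,
                             tallies_correct=correct)


def per_phase_summary(session: ParticipantSession,
                      bank: StimulusBank) -> dict[str, SDTSummary]:
    """SDT summaries per phase window (start / middle / end) and overall.

    Practice clips are excluded.  The prevalence s entering the optimal
    criterion is computed from the realized locations of each window (clip
    order is randomized, so phase composition varies by participant).
    """
    practice_ids = {c.clip_id for c in bank.practice_clips}
    phases = partition_phases(session.order, practice_ids)
    game_responses = [r for r in session.responses if r.clip_id not in practice_ids]

    def window_summary(clip_ids: set[str]) -> SDTSummary:
        counts = tally_counts(game_responses, clip_ids)
        s = counts.n_signal / counts.n_total
        return summarize_counts(counts, s)

    out = {}
    for w in ("start", "middle", "end"):
        out[w] = window_summary({c for c, ph in phases.items() if ph == w})
    out["overall"] = window_summary(set(phases))
    return out


def cohort_metrics_frame(sessions: Sequence[ParticipantSession],
                         bank: StimulusBank) -> pd.DataFrame:
    """Tidy per-participant × window metric table for the inference stage."""
    practice_ids = {c.clip_id for c in bank.practice_clips}
    rows = []
    for s in sessions:
        phases = partition_phases(s.order, practice_ids)
        summaries = per_phase_summary(s, bank)
        rt_by_phase = {w: np.mean([s.clip_rt[c] for c, ph in phases.items()
                                   if ph == w]) for w in ("start", "middle", "end")}
        pcu = (pcu_score(s.counting_span).pcu
               if s.counting_span is not None else np.nan)
        for w, summ in summaries.items():
            rows.append({
                "participant_id": s.participant_id, "group": s.profile.group,
                "window": w, "hit_rate": summ.hit_rate, "fa_rate": summ.fa_rate,
                "raw_hit_rate": summ.counts.hits / summ.counts.n_signal,
                "raw_fa_rate": summ.counts.false_alarms / summ.counts.n_noise,
                "accuracy": summ.accuracy,
                "logit_accuracy": safe_logit_accuracy(summ.counts),
                "d_prime": summ.d_prime, "lambda_obs": summ.lambda_obs,
                "lambda_opt": summ.lambda_opt, "bias": summ.bias,
                "prevalence_s": summ.prevalence_s,
                "rt_s": rt_by_phase.get(w, np.nan), "pcu": pcu,
            })
    return pd.DataFrame(rows)
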