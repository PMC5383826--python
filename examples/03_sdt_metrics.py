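"""Per-phase signal-detection measures and working-memory (PCU) scoring.

Hit/false-alarm rates get the log-linear correction (add 0.5 to hits and
false alarms, 1 to trial counts); d' = z(hit) - z(fa); the observed
criterion is -z(fa); the optimal criterion d'/2 - logit(s)/d' accounts for
targets being more prevalent than empties (s = 45/79); bias is their
difference.
"""

from sagame import (CHILD_PROFILE, generate_bank, pcu_score, per_phase_summary,
                    randomize_order, simulate_counting_span, simulate_responses)

bank = generate_bank(seed=7)
order = randomize_order(bank, seed=3)
session = simulate_responses(CHILD_PROFILE, bank, order, seed=3)

print(f"{'window':8} {'hit':>6} {'fa':>6} {'d_prime':>8} {'lam_obs':>8} "
      f"{'lam_opt':>8} {'bias':>7} {'acc':>6}")
for window, s in per_phase_summary(session, bank).items():
    print(f"{window:8} {s.hit_rate:6.3f} {s.fa_rate:6.3f} {s.d_prime:8.3f} "
          f"{s.lambda_obs:8.3f} {s.lambda_opt:8.3f} {s.bias:7.3f} "
          f"{s.accuracy:6.3f}")
print("(bias near 0 = criterion close to the accuracy-optimal one; "
      "negative = trigger-happy)")

transcript = simulate_counting_span(CHILD_PROFILE.wm_capacity,
                                    CHILD_PROFILE.wm_noise, seed=3)
score = pcu_score(transcript)
print(f"\ncounting span: {len(transcript.trials)} trials administered, "
      f"stopped early: {transcript.stopped_early}")
print(f"PCU = {score.pcu:.3f}  (mean per-trial proportion of tallies "
      "recalled in the right position)")
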