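"""Simulate one observer through the game and score their play.

The observer is an equal-variance SDT responder: evidence ~ Normal(0,1) at
empty locations, Normal(d',1) at targets, selected when above the criterion.
Scoring: hit +5, miss -5, correct rejection +1, false alarm 0; the running
total is clamped at zero after each clip.
"""

from sagame import CHILD_PROFILE, generate_bank, randomize_order, simulate_responses
from sagame.game import score_session

bank = generate_bank(seed=7)
order = randomize_order(bank, seed=3)
session = simulate_responses(CHILD_PROFILE, bank, order, seed=3,
                             participant_id="c001")

events, board = score_session(session, bank)
hits = sum(e.outcome == "hit" for e in events)
misses = sum(e.outcome == "miss" for e in events)
fas = sum(e.outcome == "false_alarm" for e in events)
crs = sum(e.outcome == "correct_rejection" for e in events)

print(f"outcomes over {len(events)} locations (incl. practice): "
      f"{hits} hits, {misses} misses, {fas} false alarms, {crs} correct rejections")
print(f"final points (zero-floored running total): {board.final_points}")
print(f"unclamped points 5*H - 5*M + CR = {board.unclamped_final}")
print("first response times (s):",
      [round(session.clip_rt[c], 2) for c in order[:5]],
      "- lognormal, mean falling across phases (learning)")
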