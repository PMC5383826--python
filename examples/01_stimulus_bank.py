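"""Generate a synthetic stimulus bank and check its structure.

The bank mimics a hazard-anticipation video game: 30 game clips plus 3
practice clips, each masked at a predefined moment, probing 2-3 screen
locations that hold an overt target (visible road user), a covert target
(occlusion someone could emerge from) or nothing.
"""

from sagame import generate_bank, randomize_order, validate_bank

bank = generate_bank(seed=7)
kinds = [l.kind for c in bank.game_clips for l in c.locations]
durations = [c.duration for c in bank.game_clips]

print("violations:", validate_bank(bank))
print(f"game clips: {len(bank.game_clips)}, practice: {len(bank.practice_clips)}")
print(f"locations: {kinds.count('overt')} overt, {kinds.count('covert')} covert, "
      f"{kinds.count('empty')} empty")
print(f"target prevalence s = {bank.prevalence:.4f}  (45/79: the SDT prior "
      "entering the optimal criterion)")
print(f"durations: mean {sum(durations) / len(durations):.2f} s, "
      f"min {min(durations):.2f}, max {max(durations):.2f}")
print("presentation order (practice first, game permuted):",
      randomize_order(bank, seed=1)[:6], "...")
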