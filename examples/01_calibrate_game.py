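"""Calibrate the contest payoff from its printed anchors and solve the game.

The symmetric payoff conditions (both players at 0.1 earn 3.45 cents, at 3
earn 2 cents, at 6 earn 0.5 cents) identify the affine contest family
g*x/(x+y) - c*x + b; the best reply and its fixed point (the one-period Nash
action) follow in closed form.
"""

from contestlearn import game

params = game.calibrate([(0.1, 3.45), (3.0, 2.0), (6.0, 0.5)])
print(f"gain_scale = {params.gain_scale:g} cents")
print(f"cost_rate  = {params.cost_rate:g} cents per action unit")
print(f"baseline   = {params.baseline:g} cents")

nash = game.nash_action(params)
print(f"\nNash action: {nash:g} (fixed point of the best-reply map)")
print(f"Nash payoff: {game.symmetric_payoff(nash, params):g} cents/period")
print(f"cooperative payoff at {params.action_min}: "
      f"{game.symmetric_payoff(params.action_min, params):g} cents/period")
print(f"competitive payoff at {params.action_max}: "
      f"{game.symmetric_payoff(params.action_max, params):g} cents/period")

print(f"\nbest reply to 0.1: {game.best_reply(0.1, params):.4f}")
print(f"relative payoff of 6 vs 0.1: {game.relative_payoff(6, 0.1, params):.4f} cents")
print("-> the higher action always wins relatively, but joint profits are "
      "maximal at the lowest action: the competition/cooperation tension.")
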