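"""Benchmark dynamics of the four learning heuristics in paired play.

Three archetypes: myopic best repliers converge to the Nash action 3;
imitate-the-best pairs escalate to maximal competition; synchronized
win-continue-lose-reverse pairs descend to the cooperative bound 0.1.
"""

import numpy as np

from contestlearn import game
from contestlearn.heuristics import AgentSpec, run_pair

params = game.default_params()

br = AgentSpec("myopic_br")
t = run_pair(br, br, 20, params, initial_actions=(0.5, 5.5), rng=0, action_grid=None)
print(f"myopic best reply, period 20: {t.actions[19]}  (Nash = 3)")

im = AgentSpec("imitate_best", adherence=1.0, inertia=0.3, tremble_sd=0.1)
t = run_pair(im, im, 300, params, rng=0, action_grid=None)
print(f"imitate-the-best with trembles, long-run median action: "
      f"{np.median(t.actions[150:]):.2f}  (escalates above Nash)")

wc = AgentSpec("wclr", step_size=0.25, wclr_initial_direction=-1)
t = run_pair(wc, wc, 200, params, initial_actions=(4.0, 4.0), rng=0)
print(f"synchronized WCLR, final profile: {t.actions[-1]}  "
      f"(joint-profit maximum at {params.action_min})")
print(f"  final payoff per player: {t.payoffs_cents[-1][0]:.2f} cents "
      f"vs {game.symmetric_payoff(3.0, params):.2f} at Nash")
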