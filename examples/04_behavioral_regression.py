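"""The behavioral regression: which heuristic explains the direction of
action changes, and how does payoff information shift heuristic use?

Codes every subject-period action change into the heuristic dummies
(COPY_UP, COPY_DOWN, WCLR, BR, interactions with the INFO treatment dummy)
and fits the linear probability model with pair-clustered standard errors,
separately for the naive phase (periods 1-25) and the rest (26-600).
"""

from contestlearn import features, inference, synth
from contestlearn.inference import wald_combination

trajs = synth.generate_experiment(seed=1)
table, log = features.code_features(trajs)
print(f"coded {log.emitted_rows} subject-period changes "
      f"({log.zero_change_rows} unchanged periods dropped, "
      f"{log.br_ties} exact best-reply ties coded 0)")

for label, window in (("periods 1-25", (1, 25)), ("periods 26-600", (26, 600))):
    res = inference.fit_lpm(table, periods=window)
    print(f"\n{label}: n={res.nobs}, clusters={res.n_clusters}, R2={res.r_squared:.3f}")
    print(res.summary_frame().round(3).to_string())

res = inference.fit_lpm(table, periods=(26, 600))
for name, weights in (
    ("imitation in Info (COPY_UP + COPY_UP:INFO)", {"copy_up": 1.0, "copy_up:info": 1.0}),
    ("best reply in Info (BR + BR:INFO)", {"br": 1.0, "br:info": 1.0}),
    ("WCLR in Info (WCLR + WCLR:INFO)", {"wclr": 1.0, "wclr:info": 1.0}),
):
    wt = wald_combination(res, weights)
    print(f"\nWald, {name}: stat={wt.statistic:.2f} p={wt.pvalue:.4f}")
print("-> Info subjects follow best reply, not imitation; the "
      "pro-cooperative WCLR heuristic loads mainly in NoInfo.")
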