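"""Generate the default synthetic experiment and reproduce the aggregate
treatment comparison: two treatments (Info / NoInfo), 18 pairs each, 600
periods, phases cut at periods 25 and 300.

NoInfo agents start as imitators and switch to pro-cooperative heuristics
around period 25; Info agents mostly stick with myopic best reply.  The
printed tests show the headline pattern: payoff information hampers
long-run cooperation.
"""

from contestlearn import inference, synth

trajs = synth.generate_experiment(seed=1)

print(inference.phase_summary(trajs).round(3).to_string(index=False))

for phase in ("naive", "longrun"):
    mw = inference.mann_whitney_treatments(trajs, phase)
    print(f"\n{phase}: treatment difference, Mann-Whitney U={mw.statistic:g} "
          f"p={mw.pvalue:.4f} (pair-level medians, n={mw.n})")
    for treatment in ("NoInfo", "Info"):
        tt = inference.t_test_vs_nash(trajs, treatment, phase)
        print(f"  {treatment:6s} vs Nash action 3: t={tt.statistic:+.2f} "
              f"p={tt.pvalue:.4f} (pair-level means)")

_, medians = inference.earnings(trajs, phase="longrun")
print(f"\nlong-run median earnings: NoInfo {medians['NoInfo']:.2f} EUR, "
      f"Info {medians['Info']:.2f} EUR")
print("-> the information-rich treatment earns less in the long run: "
      "best-reply play locks pairs near Nash while NoInfo pairs cooperate.")
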