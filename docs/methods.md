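# Methods

## The contest game and its calibration

The payoff family is the affine contest
$\pi(x_i,x_j) = g\,x_i/(x_i+x_j) - c\,x_i + b$ on the action space
$[0.1, 6]$, computed internally in euro cents per period (all anchor values
are stated in cents; points are cents times `points_per_euro / 100`, euro
are points over `points_per_euro` = 2,000). `game.calibrate` recovers
$(g, c, b)$ from linear conditions: each symmetric anchor $(x, p)$
contributes $g/2 - c x + b = p$ and an optional Nash action $x^*$
contributes the first-order condition $g = 4 c x^*$. Overdetermined systems
are accepted but every supplied condition must hold to within $10^{-9}$
cents, otherwise calibration fails with the residuals.

Symmetric anchors alone cannot separate $g$ from $b$ (symmetric payoffs
depend only on $g/2 + b$). When no Nash condition is supplied the split is
closed with the normalization $g = 2 c \cdot x_{\max}$: the minimal prize
scale under which a higher action earns a weakly higher relative payoff on
the *entire* action space ($g/(x_i+x_j) \ge c$ up to the maximal profile),
which equivalently places the interior Nash action at the midpoint
$x_{\max}/2$ of the action space. Under this normalization the three
printed anchors and the printed Nash facts are mutually consistent, so
calibrating on any three of the four conditions reproduces the fourth.
Calibrated parameters are snapped to 12 decimals when the snapped solution
still satisfies all conditions; this keeps knife-edge identities (e.g. the
best reply to an opponent at exactly 3 being exactly 3) representable, so
exact best-reply ties can occur and be counted downstream.

Numerical conventions: actions outside bounds raise immediately naming the
value; the best-reply closed form $\sqrt{g x_j/c} - x_j$ is clipped to the
bounds and is validated in tests against a $10^{-5}$-grid search oracle.

## Heuristics and the execution layer

Four decision rules are implemented as pure functions of the last period(s):
imitate-the-best (copy the opponent's previous action iff it was strictly
higher *and* earned strictly more), match (copy unconditionally), myopic
best reply (jump to the best reply against the opponent's previous action),
and win-continue-lose-reverse (WCLR: repeat the previous own adjustment
direction if own payoff rose, reverse if it fell). `prescribe_wclr` needs
two lagged periods; with a zero previous adjustment it prescribes nothing,
and with an exactly constant payoff it continues the previous direction
(mirroring the feature-coding convention below).

The execution layer (`step_agent`) makes rules stochastic and human-like:

* **inertia** — probability of leaving the slider untouched in a period
  (subjects often wait between adjustments);
* **adherence** — probability of following the active rule when moving;
  with the complementary probability the agent explores with a uniform
  draw over the action space;
* **tremble** — additive Gaussian noise applied whenever the slider moves,
  then clipped to bounds;
* **switching** — an optional period from which a different rule replaces
  the initial one (the two-tier structure: naive heuristics early, adapted
  heuristics later).

Two engine-level choices matter and are deliberate:

1. **WCLR with waiting.** Under inertia the strict one-lag WCLR loses its
   direction in every waiting spell and degenerates into a random walk, so
   the engine's WCLR treats "the previous adjustment" as the most recent
   period in which the slider actually moved, judges it by the payoff
   change since just before that move, and *holds course* while the partner
   has not yet reacted at all. When both players move every period this
   reduces exactly to the strict rule, and noiseless synchronized WCLR
   pairs converge to the cooperative bound 0.1 from every combination of
   seeding directions. When WCLR has no direction at all (the slider never
   moved) the engine seeds a random $\pm$step nudge; `AgentSpec` can pin
   this direction for fully deterministic experiments.
2. **Slider resolution.** `run_pair` snaps actions to a 0.01-unit grid by
   default (configurable, `None` for a continuous slider). A graphical
   slider has finite resolution, and the analysis conventions only bind on
   a grid: with truly continuous actions, exact action ties and exactly
   constant payoffs are measure-zero events, and the treatment dummy would
   be perfectly collinear with its copy-dummy interactions (within one
   treatment `copy_up + copy_down` would equal 1 in every row), making the
   full interaction regression unidentifiable.

Moves are simultaneous with one-period memory: both agents choose at $t$
from the history through $t-1$; target rules jump fully to their target
(partial adjustment is expressible through adherence).

## The synthetic experiment

`synth.generate_experiment` emulates the experimental design: two
treatments, 18 independent pairs each, 600 periods, uniform random initial
slider positions, and it stores every subject's ground-truth `AgentSpec`.
Defaults encode the narrative the aggregate data suggests — NoInfo subjects
all start on imitate-the-best and switch (probability 1.0) to a 50/50
mixture of match and WCLR at a per-subject geometric switch period with
mean 25; Info subjects play myopic best reply and switch to the same
pro-cooperative mixture only with probability 0.10 around period 150 (less
likely and later: payoff information makes the best-reply heuristic hard to
abandon). Switch periods are drawn per subject rather than imposed as a
common changepoint because the analysis phase cut at period 25 is a
reporting convention, not a behavioral law.

Execution parameters are drawn per subject from uniform ranges to emulate
subject heterogeneity: adherence U(0.90, 0.99), inertia U(0.30, 0.60),
WCLR step U(0.20, 0.50) action units, tremble s.d. U(0.03, 0.12). No
quantitative behavioral noise levels are published for this design, so
these ranges are free parameters of the generator; they were chosen (and
are documented here) solely so that the *ordinal* treatment patterns hold —
NoInfo above the Nash action in the naive phase and significantly below it
in the long run, Info statistically indistinguishable from Nash in the long
run, NoInfo long-run earnings above Info — and no claim is made of matching
any published moment or coefficient. The master seed fans out through
`numpy.random.SeedSequence.spawn` with one child stream per pair, so a
pair's path is invariant to how many pairs are generated.

What the generator does **not** emulate: session effects, within-session
learning spillovers, partner rematching, attention drift over 80-minute
sessions, or any deliberate experimentation policy beyond uniform
exploration. Passing tests therefore show that the *pipeline* recovers the
structure of a known data-generating process of this shape — not that real
subjects follow these exact rules.

## Feature coding

For every subject-period $t \ge 3$ with a changed own action, one row is
emitted (periods 1–2 lack the lags; unchanged periods are dropped because
the binary outcome records only the direction of change):

* `change` = 1 iff the own action rose from $t-1$ to $t$;
* `copy_up` / `copy_down` = 1 iff the opponent's action at $t-1$ was
  strictly higher / lower than the own action at $t-1$;
* `wclr` = 1 iff WCLR prescribes an increase from the own adjustment
  $t-2 \to t-1$ and the own payoff change over the same step; an exactly
  constant payoff codes 1 (variants: code 0, or drop those rows — the
  constant-profit sentinel is kept as a column so variants are loss-free);
  a zero previous adjustment codes 0 and is counted in the coding log;
* `br` = 1 iff the best reply to the opponent's action at $t-1$ is
  strictly above the own action at $t-1$; exact ties code 0 and are
  counted;
* `at_boundary` = 1 iff the previous own action sits within $10^{-12}$ of
  an action bound (there the direction of change is mechanically one-sided;
  a filter switch drops such rows as a robustness check);
* phases: naive $\le 25$ < learning $\le 300$ < longrun, cutoffs
  configurable.

Comparisons use exact floating equality on stored actions (the engine's
grid makes exact equality meaningful); the boundary tolerance applies only
to boundary detection. The coding log satisfies the accounting identity
`emitted + zero_change + warmup = total subject-periods`.

## Estimation and testing

The linear probability model regresses `change` on the four heuristic
dummies, the treatment dummy, and all four interactions, by OLS with
one-way cluster-robust (sandwich) covariance on pairs and the conventional
small-sample factor $\frac{G}{G-1}\cdot\frac{N-1}{N-K}$ (with one
observation per cluster this reduces exactly to HC1). Rank-deficient
designs fail with the names of the collinear columns. A Logit estimator is
available behind the same interface as a robustness variant; only
sign-agreement with the LPM is asserted. Wald tests of linear coefficient
combinations use the clustered covariance; for a single coefficient the
statistic reduces to the squared t ratio.

Aggregate statistics follow the descriptive conventions of the design:
median actions in 5-period bins up to period 25 and 25-period bins after;
pooled subject-period action moments per treatment and phase (a pair-level
variant is exposed); a two-sided Mann-Whitney U test comparing treatments;
a two-sided one-sample t test against the Nash action; and phase earnings
as summed points over 2,000 (a show-up fee is added only for session-payout
reporting). Tests default to **pair-level** units (medians for the rank
test, means for the t test) because pairs are the independent observational
units; subject-level variants are exposed but not default.

## Problem sizes used in validation

The test suite validates parameter recovery on single-rule populations of
18 pairs x 600 periods (fixed seeds), the WCLR-adherence monotonicity on
10 replicates of 8 pairs x 400 periods per adherence level in
{0.3, 0.6, 0.9}, and the qualitative treatment pattern on the default
18-pair, 600-period experiment at seed 1, including phase-cutoff shifts of
plus or minus 20 percent. The imitation-population recovery fit drops
boundary rows (imitation saturates at the competitive bound, where change
directions are mechanically one-sided).

## Known limitations

* The generator's behavioral parameters are unidentified free choices;
  only ordinal patterns are claimed.
* The engine's WCLR memory variant is a modeling choice for asynchronous
  play; the coding layer deliberately keeps the strict one-lag definition,
  so recovered WCLR coefficients are attenuated relative to a coder that
  knew the engine's rule.
* Matching pairs (both subjects on `match`) have no payoff anchor and
  drift; they add realistic cross-pair dispersion but are not a model of
  deliberate coordination.
* Only the symmetric two-player game is supported; no rematching, no
  asymmetric contest exponents, no n > 2.
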